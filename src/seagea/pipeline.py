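"""End-to-end orchestration: QC -> spatial -> environment -> GEA ->
structure -> enrichment, from one YAML-serializable configuration.

Every stage draws its randomness from a seed derived deterministically from
the global seed and the stage name, so identical config + inputs give a
byte-identical report and stages can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envsel, gearda, genoqc, popstruct, seaspace
from .enrich import classify_context, fisher_enrichment, load_go_map
from .simgen import read_mask_asc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds; defaults are the study's stated values."""

    vcf: str = ""
    samples: str = ""
    env: str = ""
    mask: str = ""
    gff: str | None = None
    go_map: str | None = None
    truth: str | None = None

    max_locus_missing: float = 0.2
    min_mac: int = 3
    relatedness_threshold: float = 0.5
    min_overlap: int = 50

    snap_radius_km: float = 50.0
    mem_alpha: float = 0.05
    mem_n_perm: int = 100

    r_max: float = 0.7
    vif_max: float = 3.0
    env_alpha: float = 0.05
    env_n_perm: int = 1000

    anova_n_perm: int = 1000
    axis_alpha: float = 0.05
    sd_mult: float = 3.0

    fst_n_perm: int = 10000
    fst_q: float = 0.10
    k_min: int = 1
    k_max: int = 9
    cv_replicates: int = 10
    run_cv: bool = True

    enrich_q: float = 0.05
    promoter_bp: int = 2000

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


@dataclass
class PipelineResult:
    report: dict
    genotypes: genoqc.GenotypeMatrix
    candidates: gearda.CandidateSet | None
    model: gearda.RDAModel | None
    artifacts: dict = field(default_factory=dict)


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def _drop_aliased(X: np.ndarray, names: list[str], Z: np.ndarray, rtol: float = 1e-8):
    """Drop predictor columns collinear with [1, Z, earlier predictors].

    Mirrors the aliasing behaviour of constrained-ordination software: with
    site-level predictors and several site-level spatial conditioners the
    combined design can be exactly rank-deficient; aliased variables are
    removed in order and reported rather than aborting the fit.
    """
    n = X.shape[0]
    basis = np.empty((n, 0))
    if Z.shape[1]:
        Q, _ = np.linalg.qr(Z - Z.mean(axis=0))
        basis = Q
    kept, aliased = [], []
    for j, name in enumerate(names):
        x = X[:, [j]] - X[:, j].mean()
        norm0 = np.linalg.norm(x)
        r = x - basis @ (basis.T @ x) if basis.shape[1] else x
        if np.linalg.norm(r) <= rtol * max(norm0, 1.0):
            aliased.append(name)
            continue
        kept.append(j)
        basis = np.hstack([basis, r / np.linalg.norm(r)])
    return kept, aliased


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run all stages; writes report.json / report.txt and per-stage CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": 1, "config": _jsonable(asdict(config))}
    artifacts: dict = {}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---------------------------------------------------------------- QC
    _stage("qc")
    try:
        G = genoqc.load_genotypes(config.vcf)
        n0, l0 = G.n_individuals, G.n_loci
        G = genoqc.filter_loci(G, config.max_locus_missing, min_mac=0)
        l_miss = G.n_loci
        R = genoqc.pairwise_relatedness(G, min_overlap=config.min_overlap)
        G, removed = genoqc.prune_related(G, R, threshold=config.relatedness_threshold)
        G = genoqc.filter_loci(G, config.max_locus_missing, min_mac=config.min_mac)
    except Exception as exc:
        fail("qc", exc)
    report["qc"] = {
        "input_individuals": n0,
        "input_loci": l0,
        "loci_after_missing_filter": l_miss,
        "individuals_removed_related": sorted(removed),
        "individuals_retained": G.n_individuals,
        "loci_retained": G.n_loci,
    }
    qc_log = outdir / "qc_removed.tsv"
    pd.DataFrame(
        [{"id": r, "reason": f"|R| >= {config.relatedness_threshold}"} for r in sorted(removed)]
    ).to_csv(qc_log, sep="\t", index=False)
    artifacts["qc_removed"] = str(qc_log)

    samples = pd.read_csv(config.samples).set_index("sample_id")
    sample_sites = [samples.loc[sid, "site"] for sid in G.sample_ids]
    site_names = list(pd.unique(np.asarray(sample_sites, dtype=object)))
    site_index = np.asarray([site_names.index(s) for s in sample_sites])
    Y = gearda.impute_dosage(G)

    # ------------------------------------------------------------ spatial
    _stage("spatial")
    try:
        mask = read_mask_asc(config.mask)
        centroids = [
            (
                samples.loc[[sid for sid in G.sample_ids if samples.loc[sid, "site"] == s], "lon"].mean(),
                samples.loc[[sid for sid in G.sample_ids if samples.loc[sid, "site"] == s], "lat"].mean(),
            )
            for s in site_names
        ]
        D = seaspace.oceanic_distances(
            centroids, mask, labels=site_names, snap_radius_km=config.snap_radius_km
        )
        basis = seaspace.build_dbmem(D)
        mem_sel = seaspace.forward_select_mems(
            Y, basis, site_index=site_index, alpha=config.mem_alpha,
            n_perm=config.mem_n_perm, seed=stage_seed(config.seed, "spatial"),
        )
    except Exception as exc:
        fail("spatial", exc)
    Z = seaspace.expand_to_individuals(basis.vectors[:, mem_sel.selected], site_index)
    report["spatial"] = {
        "truncation_km": basis.truncation_distance,
        "n_mem_candidates": basis.vectors.shape[1],
        "mems_selected": [f"MEM{i + 1}" for i in mem_sel.selected],
        "mem_pvalues": mem_sel.pvalues,
        "global_p": mem_sel.global_p,
    }
    mem_csv = outdir / "mems.csv"
    pd.DataFrame(
        Z, columns=[f"MEM{i + 1}" for i in mem_sel.selected]
    ).assign(sample_id=G.sample_ids).set_index("sample_id").to_csv(mem_csv)
    artifacts["mems"] = str(mem_csv)

    # ---------------------------------------------------------------- env
    _stage("env")
    try:
        env_df = pd.read_csv(config.env)
        if "site" in env_df.columns:
            E = envsel.broadcast_to_individuals(env_df, sample_sites)
        else:
            E = envsel.EnvMatrix(
                env_df.set_index("sample_id").loc[G.sample_ids].to_numpy(dtype=float),
                [c for c in env_df.columns if c != "sample_id"],
                row_ids=G.sample_ids,
            )
        E = envsel.standardize_env(E)
        kept, drop_log = envsel.collinearity_prune(E, config.r_max, config.vif_max)
        E_pruned = E.select(kept)
        env_sel = envsel.forward_select_env(
            Y, E_pruned, alpha=config.env_alpha, n_perm=config.env_n_perm,
            seed=stage_seed(config.seed, "env"),
        )
    except Exception as exc:
        fail("env", exc)
    retained = [kept[i] for i in env_sel.selected]
    report["env"] = {
        "candidates": E.names,
        "kept_after_collinearity": kept,
        "drop_log": _jsonable(drop_log),
        "retained": retained,
        "pvalues": env_sel.pvalues,
        "global_p": env_sel.global_p,
    }
    E_ret = E_pruned.select(retained) if retained else None
    if retained:
        env_csv = outdir / "env_retained.csv"
        E_ret.to_frame().to_csv(env_csv, index=False)
        artifacts["env_retained"] = str(env_csv)

    # ---------------------------------------------------------------- GEA
    model = None
    candidates = None
    aliased: list[str] = []
    if retained:
        kept_idx, aliased = _drop_aliased(E_ret.values, retained, Z)
        if aliased:
            logger.warning("gea: dropping aliased predictors %s", aliased)
            retained = [retained[i] for i in kept_idx]
            E_ret = E_ret.select(retained) if retained else None
            report["env"]["retained"] = retained
            report["env"]["aliased_given_mems"] = aliased
    if not retained:
        report["gea"] = {"skipped": "no environmental variable retained"}
    else:
        _stage("gea")
        try:
            model = gearda.partial_rda(
                Y, E_ret.values, Z if Z.shape[1] else None,
                env_names=retained, mem_indices=mem_sel.selected, locus_ids=G.locus_ids,
            )
            seed_a = stage_seed(config.seed, "gea")
            overall = gearda.permutation_significance(model, "overall", config.anova_n_perm, seed_a)
            terms = gearda.permutation_significance(model, "term", config.anova_n_perm, seed_a + 1)
            axes = gearda.permutation_significance(model, "axis", config.anova_n_perm, seed_a + 2)
            sig_axes = [i for i, t in enumerate(axes) if t.pvalue <= config.axis_alpha]
            if sig_axes:
                candidates = gearda.detect_candidates(model, sig_axes, config.sd_mult)
                candidates = gearda.assign_predictors(candidates, G, E_ret.values, retained)
        except Exception as exc:
            fail("gea", exc)
        report["gea"] = {
            "variance_partition": _jsonable(model.variance_partition),
            "eigenvalues": _jsonable(model.eigenvalues),
            "axis_share_of_constrained": _jsonable(
                model.eigenvalues / model.eigenvalues.sum()
                if model.eigenvalues.sum() > 0 else model.eigenvalues
            ),
            "overall": {"F": overall[0].statistic, "p": overall[0].pvalue},
            "terms": {t.label: {"F": t.statistic, "p": t.pvalue} for t in terms},
            "axes": {t.label: {"F": t.statistic, "p": t.pvalue} for t in axes},
            "significant_axes": [a + 1 for a in sig_axes],
            "n_candidates": 0 if candidates is None else len(candidates),
        }
        if candidates is not None and len(candidates):
            cand_csv = outdir / "candidates.csv"
            candidates.table.to_csv(cand_csv, index=False)
            artifacts["candidates"] = str(cand_csv)
            report["gea"]["best_predictor_counts"] = _jsonable(
                candidates.table["best_predictor"].value_counts().sort_index().to_dict()
            )

    # ---------------------------------------------------------- structure
    if candidates is None or len(candidates) < 2:
        report["structure"] = {"skipped": "fewer than 2 candidate loci"}
    else:
        _stage("structure")
        try:
            cand_idx = [G.locus_ids.index(lid) for lid in candidates.locus_ids]
            Gc = G.take_loci(cand_idx)
            labels = np.asarray(sample_sites, dtype=object)
            div = popstruct.diversity_by_site(Gc, labels)
            fst = popstruct.pairwise_fst(
                Gc, labels, n_perm=config.fst_n_perm, q=config.fst_q,
                seed=stage_seed(config.seed, "fst"),
            )
            Yc = gearda.impute_dosage(Gc)
            scores, frac = popstruct.genotype_pca(Yc)
            k_range = range(config.k_min, min(config.k_max, Gc.n_individuals) + 1)
            k_table, best_k = popstruct.choose_k(
                Gc.dosage, k_range, method="AIC", seed=stage_seed(config.seed, "chooseK"),
            )
            if config.run_cv:
                cv_table, best_k_cv = popstruct.choose_k(
                    Gc.dosage, k_range, method="CV", cv_replicates=config.cv_replicates,
                    seed=stage_seed(config.seed, "chooseK_cv"),
                )
                k_table["cv_error"] = cv_table["cv_error"]
            else:
                best_k_cv = None
            fit = popstruct.em_cluster(
                Gc.dosage, best_k, seed=stage_seed(config.seed, "admixture")
            )
            neutral_idx = [i for i in range(G.n_loci) if i not in set(cand_idx)]
            theta_cand = popstruct.wc_theta(Gc.dosage, labels)
            theta_neut = popstruct.wc_theta(G.take_loci(neutral_idx).dosage, labels)
        except Exception as exc:
            fail("structure", exc)
        report["structure"] = {
            "diversity": _jsonable(div.to_dict(orient="records")),
            "n_significant_fst_pairs": int(np.sum(np.triu(fst.significant, 1))),
            "mean_pairwise_fst_candidates": float(np.mean(fst.theta[np.triu_indices(len(fst.sites), 1)])),
            "global_fst_candidates": theta_cand,
            "global_fst_noncandidates": theta_neut,
            "pca_explained_first3": _jsonable(frac[:3]),
            "best_k_aic": best_k,
            "best_k_cv": best_k_cv,
            "k_table": _jsonable(k_table.to_dict(orient="records")),
        }
        for name, frame in {
            "diversity": div,
            "fst": fst.to_frame(),
            "k_table": k_table,
            "q_matrix": pd.DataFrame(
                fit.membership, columns=[f"Q{k + 1}" for k in range(fit.K)]
            ).assign(sample_id=Gc.sample_ids).set_index("sample_id").reset_index(),
        }.items():
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            artifacts[name] = str(path)

    # ---------------------------------------------------------- enrichment
    if candidates is None or not len(candidates) or not (config.gff and config.go_map):
        report["enrichment"] = {"skipped": "no candidates or no annotation inputs"}
    else:
        _stage("enrichment")
        try:
            contexts = classify_context(
                G.locus_ids, G.contigs, G.positions, config.gff, config.promoter_bp
            )
            go_map = load_go_map(config.go_map)
            enr = fisher_enrichment(
                candidates.locus_ids, G.locus_ids, go_map, q=config.enrich_q
            )
        except Exception as exc:
            fail("enrichment", exc)
        cand_ctx = contexts[contexts["locus_id"].isin(set(candidates.locus_ids))]
        report["enrichment"] = {
            "candidate_context_counts": _jsonable(
                cand_ctx["context"].value_counts().sort_index().to_dict()
            ),
            "n_terms_tested": int(len(enr)),
            "n_terms_significant": int(enr["significant"].sum()) if len(enr) else 0,
            "significant_terms": sorted(enr.loc[enr["significant"], "term"].tolist())
            if len(enr) else [],
        }
        ctx_csv = outdir / "contexts.csv"
        contexts.to_csv(ctx_csv, index=False)
        enr_csv = outdir / "enrichment.csv"
        enr.to_csv(enr_csv, index=False)
        artifacts["contexts"] = str(ctx_csv)
        artifacts["enrichment"] = str(enr_csv)

    # ---------------------------------------------------------- truth check
    if config.truth and candidates is not None:
        truth = pd.read_csv(config.truth)
        adaptive = set(truth.loc[truth["is_adaptive"].astype(bool), "locus_id"])
        retained_adaptive = adaptive & set(G.locus_ids)
        flagged = set(candidates.locus_ids)
        tp = len(flagged & retained_adaptive)
        report["truth_recovery"] = {
            "n_planted_adaptive_retained": len(retained_adaptive),
            "n_flagged": len(flagged),
            "true_positives": tp,
            "sensitivity": tp / len(retained_adaptive) if retained_adaptive else None,
            "false_discovery_rate": (len(flagged) - tp) / len(flagged) if flagged else None,
        }

    report = _jsonable(report)
    report_json = outdir / "report.json"
    with open(report_json, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["report"] = str(report_json)
    _write_text_report(report, outdir / "report.txt")
    artifacts["report_txt"] = str(outdir / "report.txt")
    return PipelineResult(
        report=report, genotypes=G, candidates=candidates, model=model, artifacts=artifacts
    )


def _write_text_report(report: dict, path) -> None:
    lines = ["seagea pipeline report", "=" * 24]
    qc = report.get("qc", {})
    lines.append(
        f"QC: {qc.get('input_individuals')} -> {qc.get('individuals_retained')} individuals, "
        f"{qc.get('input_loci')} -> {qc.get('loci_retained')} loci"
    )
    sp = report.get("spatial", {})
    lines.append(f"MEMs selected: {sp.get('mems_selected')}")
    env = report.get("env", {})
    lines.append(f"Environmental variables retained: {env.get('retained')}")
    gea = report.get("gea", {})
    if "variance_partition" in gea:
        vp = gea["variance_partition"]
        lines.append(
            f"Variance partition: conditioned={vp['conditioned']:.4f} "
            f"constrained={vp['constrained']:.4f} residual={vp['residual']:.4f}"
        )
        lines.append(
            f"Overall p={gea['overall']['p']}; significant axes: {gea.get('significant_axes')}; "
            f"candidates: {gea.get('n_candidates')}"
        )
    st = report.get("structure", {})
    if "best_k_aic" in st:
        lines.append(
            f"Best K (AIC): {st['best_k_aic']}; best K (CV): {st.get('best_k_cv')}; "
            f"significant FST pairs: {st['n_significant_fst_pairs']}"
        )
    en = report.get("enrichment", {})
    if "n_terms_significant" in en:
        lines.append(
            f"GO terms significant: {en['n_terms_significant']} of {en['n_terms_tested']}"
        )
    tr = report.get("truth_recovery")
    if tr:
        lines.append(
            f"Truth recovery: sensitivity={tr['sensitivity']}, FDR={tr['false_discovery_rate']}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
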