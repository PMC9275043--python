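"""Synthetic seascape, environment and genotype generator with planted truth.

Emulates the sampling design the pipeline is built for: ~9 sites along a 1-D
coastline, tens of individuals per site, thousands of biallelic SNPs with ~1%
missingness, isolation-by-distance neutral structure at low F_ST, a minority
of adaptive loci whose site allele frequencies follow smooth environmental
gradients, correlated environmental variables, and a few planted duplicate
individuals.  Every generated dataset carries a truth table naming the
planted adaptive loci, so candidate recovery is measurable.

Model summary
-------------
* Neutral loci: a 1-D stepping-stone frequency chain.  Each site's frequency
  is a Beta perturbation of a migration-weighted mix of the previous site's
  frequency and the ancestral frequency; the Beta concentration is calibrated
  by bisection so the realized multilocus Weir-Cockerham F_ST matches
  ``drift_fst``.
* Adaptive loci: site frequency p_s = logistic(a0 + b * z_s), with z_s the
  standardized driving environmental variable; driving variables assigned
  round-robin, one per locus.
* Genotypes: Binomial(2, p_s) per individual; missing entries uniform at
  random at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genoqc import GenotypeMatrix, write_vcf, _orient_to_minor
from .popstruct import wc_theta

__all__ = [
    "WaterMask",
    "SimConfig",
    "make_seascape",
    "simulate_genotypes",
    "plant_relatives",
    "write_fixture",
    "generate_fixture",
    "write_mask_asc",
    "read_mask_asc",
    "DEFAULT_ENV_VARS",
]


# ---------------------------------------------------------------------------
# Water mask (ESRI ASCII grid)
# ---------------------------------------------------------------------------

@dataclass
class WaterMask:
    """Rectangular raster of water (True) / land (False) cells.

    ``grid`` row 0 is the northernmost row; ``origin_lon``/``origin_lat`` are
    the lower-left corner, matching the ESRI ASCII convention.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not self.grid.any():
            raise ValueError("mask must contain at least one water cell")

    @property
    def nrows(self) -> int:
        return self.grid.shape[0]

    @property
    def ncols(self) -> int:
        return self.grid.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat + (self.nrows - row - 0.5) * self.cell_size
        return lon, lat


def write_mask_asc(mask: WaterMask, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {mask.ncols}\n")
        fh.write(f"nrows {mask.nrows}\n")
        fh.write(f"xllcorner {mask.origin_lon}\n")
        fh.write(f"yllcorner {mask.origin_lat}\n")
        fh.write(f"cellsize {mask.cell_size}\n")
        fh.write("NODATA_value -9999\n")
        for row in mask.grid:
            fh.write(" ".join("1" if w else "0" for w in row) + "\n")


def read_mask_asc(path) -> WaterMask:
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(float(v)) for v in parts])
    try:
        grid = np.asarray(rows) > 0
        return WaterMask(
            origin_lon=header["xllcorner"],
            origin_lat=header["yllcorner"],
            cell_size=header["cellsize"],
            grid=grid,
        )
    except KeyError as exc:
        raise ValueError(f"malformed ESRI ASCII grid {path}: missing {exc}") from exc


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: name, along-coast gradient shape, site-level noise SD (variables are on a
#: standardized scale, so the SD is relative to a unit-variance gradient)
DEFAULT_ENV_VARS: tuple[tuple[str, str, float], ...] = (
    ("sst_min", "linear", 0.1),
    ("salinity_max", "sigmoid", 0.1),
    ("pp_max", "quadratic", 0.1),
    ("curvel_max", "sine", 0.1),
    ("curvel_range", "halfsine", 0.1),
)


def _default_env_correlation(k: int, names: list[str]) -> np.ndarray:
    C = np.full((k, k), 0.4)
    np.fill_diagonal(C, 1.0)
    if "curvel_max" in names and "curvel_range" in names:
        i, j = names.index("curvel_max"), names.index("curvel_range")
        C[i, j] = C[j, i] = 0.8
    return C


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic seascape."""

    n_sites: int = 9
    per_site_n: int | tuple[int, ...] = (23, 22, 22, 22, 22, 22, 22, 22, 23)
    n_neutral: int = 2000
    n_adaptive: int = 50
    env_vars: tuple[tuple[str, str, float], ...] = DEFAULT_ENV_VARS
    env_correlation: np.ndarray | None = None  # None -> package default matrix
    migration_rate: float = 0.5
    drift_fst: float = 0.02
    effect_size: float = 2.0
    adaptive_intercept: float | None = None  # None -> logit of a random base freq
    missing_rate: float = 0.01
    n_related_pairs: int = 3
    seed: int = 0
    # raster geometry (southern-ocean flavoured defaults; arbitrary units fine)
    nrows: int = 16
    ncols: int = 48
    cell_size: float = 0.05
    origin_lon: float = 129.0
    origin_lat: float = -37.0
    land_rows: int = 6
    site_cells: tuple[tuple[int, int], ...] | None = None
    # gene / GO fixture geometry
    genome_length: int = 2_000_000
    n_genes: int = 120
    promoter_bp: int = 2000
    go_n_terms: int = 30
    go_boost_term: str = "GO:0009991"

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.n_neutral <= 0:
            raise ValueError("counts must be positive")
        if self.n_adaptive < 0:
            raise ValueError("n_adaptive must be >= 0")
        if not 0 <= self.migration_rate <= 1:
            raise ValueError("migration_rate must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if np.isscalar(self.per_site_n):
            self.per_site_n = tuple([int(self.per_site_n)] * self.n_sites)
        else:
            self.per_site_n = tuple(int(v) for v in self.per_site_n)
        if len(self.per_site_n) != self.n_sites or min(self.per_site_n) <= 0:
            raise ValueError("per_site_n must give a positive count per site")
        if self.env_correlation is not None:
            C = np.asarray(self.env_correlation, dtype=float)
            k = len(self.env_vars)
            if C.shape != (k, k):
                raise ValueError("env_correlation shape must match env_vars")
            if not np.allclose(C, C.T):
                raise ValueError("env_correlation must be symmetric")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ValueError("env_correlation must be positive semi-definite")
            self.env_correlation = C

    @property
    def site_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]


# ---------------------------------------------------------------------------
# Seascape and environment
# ---------------------------------------------------------------------------

_SHAPES = {
    "linear": lambda s: s,
    "quadratic": lambda s: (s - 0.5) ** 2,
    "sigmoid": lambda s: expit(8.0 * (s - 0.5)),
    "sine": lambda s: np.sin(2.0 * np.pi * s),
    "halfsine": lambda s: np.sin(np.pi * s),
}


def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Lower-triangular-like factor L with L @ L.T = C (PSD-safe)."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 0.0, None)
        return V @ np.diag(np.sqrt(w))


def make_seascape(config: SimConfig):
    """Build the water mask, site coordinates and environmental table.

    Environmental site values are deterministic smooth functions of
    along-coast position, mixed so their noise-free pairwise correlations
    equal ``env_correlation`` exactly, plus independent Gaussian noise.
    """
    rng = np.random.default_rng([config.seed, 101])
    grid = np.ones((config.nrows, config.ncols), dtype=bool)
    grid[: config.land_rows, :] = False  # land strip along the northern edge
    mask = WaterMask(config.origin_lon, config.origin_lat, config.cell_size, grid)

    if config.site_cells is not None:
        cells = list(config.site_cells)
        if len(cells) != config.n_sites:
            raise ValueError("site_cells length must equal n_sites")
        for name, (r, c) in zip(config.site_names, cells):
            if not (0 <= r < mask.nrows and 0 <= c < mask.ncols) or not mask.grid[r, c]:
                raise ValueError(f"site {name} at cell ({r}, {c}) is on land")
    else:
        row = config.land_rows + 1
        cols = np.unique(np.round(np.linspace(1, config.ncols - 2, config.n_sites)).astype(int))
        if len(cols) < config.n_sites:
            raise ValueError("grid too narrow for the requested number of sites")
        cells = [(row, int(c)) for c in cols]

    coords = [mask.cell_center(r, c) for r, c in cells]
    s = np.linspace(0.0, 1.0, config.n_sites)
    sites = pd.DataFrame(
        {
            "site": config.site_names,
            "lon": [c[0] for c in coords],
            "lat": [c[1] for c in coords],
            "row": [rc[0] for rc in cells],
            "col": [rc[1] for rc in cells],
            "coast_pos": s,
        }
    )

    names = [v[0] for v in config.env_vars]
    k = len(names)
    env = pd.DataFrame({"site": config.site_names})
    if k:
        if config.n_sites <= k:
            raise ValueError("need more sites than environmental variables")
        raw = np.column_stack([_SHAPES[shape](s) for _, shape, _ in config.env_vars])
        Q, _ = np.linalg.qr(np.column_stack([np.ones(config.n_sites), raw]))
        B = Q[:, 1 : k + 1]
        # deterministic sign: each basis column tracks its own raw shape
        for j in range(k):
            if B[:, j] @ (raw[:, j] - raw[:, j].mean()) < 0:
                B[:, j] = -B[:, j]
        C = (
            config.env_correlation
            if config.env_correlation is not None
            else _default_env_correlation(k, names)
        )
        V = np.sqrt(config.n_sites - 1) * (B @ _psd_factor(C).T)
        noise_sd = np.array([v[2] for v in config.env_vars])
        V = V + rng.standard_normal(V.shape) * noise_sd[None, :]
        for j, name in enumerate(names):
            env[name] = V[:, j]
    return mask, sites, env


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _stepping_stone_freqs(conc: float, n_loci: int, n_sites: int, m: float, rng):
    p0 = rng.uniform(0.1, 0.9, size=n_loci)
    q = np.empty((n_sites, n_loci))
    prev = p0
    for s in range(n_sites):
        mu = (1.0 - m) * prev + m * p0
        q[s] = np.clip(rng.beta(conc * mu, conc * (1.0 - mu)), 1e-4, 1.0 - 1e-4)
        prev = q[s]
    return q


def _draw_genotypes(freqs: np.ndarray, per_site_n, rng) -> np.ndarray:
    blocks = [
        rng.binomial(2, freqs[s][None, :], size=(n_s, freqs.shape[1])).astype(float)
        for s, n_s in enumerate(per_site_n)
    ]
    return np.vstack(blocks)


def _calibrate_concentration(config: SimConfig, seed_key: int = 202) -> float:
    """Bisection on the Beta concentration so pilot-realized multilocus
    Weir-Cockerham F_ST matches ``drift_fst``."""
    n_pilot = 300
    labels = np.repeat(np.arange(config.n_sites), config.per_site_n)

    def realized(log10_a: float) -> float:
        rng = np.random.default_rng([config.seed, seed_key])
        q = _stepping_stone_freqs(
            10.0**log10_a, n_pilot, config.n_sites, config.migration_rate, rng
        )
        dos = _draw_genotypes(q, config.per_site_n, rng)
        return wc_theta(dos, labels)

    lo, hi = 0.3, 6.0  # theta decreasing in concentration
    if realized(lo) < config.drift_fst:
        return 10.0**lo
    if realized(hi) > config.drift_fst:
        return 10.0**hi
    for _ in range(25):
        mid = (lo + hi) / 2.0
        if realized(mid) > config.drift_fst:
            lo = mid
        else:
            hi = mid
    return 10.0 ** ((lo + hi) / 2.0)


_NUCS = np.array(list("ACGT"))


def simulate_genotypes(sites: pd.DataFrame, env: pd.DataFrame, config: SimConfig):
    """Generate the genotype matrix and its truth table.

    Returns a minor-allele-oriented :class:`GenotypeMatrix` (individuals
    grouped by site, ``<site>_<k>`` sample ids) and a truth table with one
    row per locus (locus_id, is_adaptive, driving_variable, effect_size).
    """
    env_names = [c for c in env.columns if c != "site"]
    if config.n_adaptive > 0 and not env_names:
        raise ValueError("n_adaptive > 0 requires at least one environmental variable")
    rng = np.random.default_rng([config.seed, 7])
    conc = _calibrate_concentration(config)
    freqs = _stepping_stone_freqs(
        conc, config.n_neutral + config.n_adaptive, config.n_sites,
        config.migration_rate, rng,
    )

    driving: list[str] = []
    if config.n_adaptive:
        E = env[env_names].to_numpy(dtype=float)
        Z = (E - E.mean(axis=0)) / E.std(axis=0, ddof=1)
        # selection acts on top of drift: the adaptive columns keep their
        # stepping-stone frequencies and gain a logit-scale environmental
        # term, so effect_size = 0 reduces exactly to the neutral model
        for i in range(config.n_adaptive):
            j = i % len(env_names)
            driving.append(env_names[j])
            col = config.n_neutral + i
            a0 = (
                config.adaptive_intercept
                if config.adaptive_intercept is not None
                else logit(freqs[:, col])
            )
            freqs[:, col] = expit(a0 + config.effect_size * Z[:, j])

    L = freqs.shape[1]
    is_adaptive = np.zeros(L, dtype=bool)
    is_adaptive[config.n_neutral :] = True
    order = rng.permutation(L)  # scatter adaptive loci through the panel
    freqs = freqs[:, order]
    is_adaptive = is_adaptive[order]
    drive_all = np.array([""] * config.n_neutral + driving, dtype=object)[order]

    dosage = _draw_genotypes(freqs, config.per_site_n, rng)
    miss = rng.random(dosage.shape) < config.missing_rate
    dosage[miss] = np.nan

    positions = np.sort(rng.choice(config.genome_length, size=L, replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4
    ref = _NUCS[ref_idx].astype(object)
    alt = _NUCS[alt_idx].astype(object)
    dosage, ref, alt, _ = _orient_to_minor(dosage, ref, alt)

    sample_ids = [
        f"{site}_{k + 1:02d}"
        for site, n_s in zip(config.site_names, config.per_site_n)
        for k in range(n_s)
    ]
    locus_ids = [f"L{i + 1:05d}" for i in range(L)]
    G = GenotypeMatrix(
        dosage=dosage,
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        contigs=np.asarray(["chr1"] * L, dtype=object),
        positions=positions,
        ref=ref,
        alt=alt,
    )
    truth = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "is_adaptive": is_adaptive,
            "driving_variable": np.where(is_adaptive, drive_all, "none"),
            "effect_size": np.where(is_adaptive, config.effect_size, 0.0),
        }
    )
    return G, truth


def site_labels(G: GenotypeMatrix) -> np.ndarray:
    """Site label of each sample (the id prefix before the first underscore)."""
    return np.asarray([sid.split("_")[0] for sid in G.sample_ids], dtype=object)


def plant_relatives(
    G: GenotypeMatrix, n_pairs: int, seed: int = 0, missing_rate: float = 0.01
) -> GenotypeMatrix:
    """Append ``n_pairs`` duplicate individuals with fresh missingness.

    Each duplicate copies a distinct randomly chosen source row; the pair is
    recorded in ``planted_pairs``.
    """
    if n_pairs < 0 or n_pairs > G.n_individuals:
        raise ValueError("n_pairs must be between 0 and the number of individuals")
    if n_pairs == 0:
        return G
    rng = np.random.default_rng([seed, 23])
    src = rng.choice(G.n_individuals, size=n_pairs, replace=False)
    new_rows = G.dosage[src].copy()
    new_rows[rng.random(new_rows.shape) < missing_rate] = np.nan
    new_ids = [f"{G.sample_ids[s]}_dup{i + 1}" for i, s in enumerate(src)]
    out = G.copy()
    out.dosage = np.vstack([G.dosage, new_rows])
    out.sample_ids = list(G.sample_ids) + new_ids
    out.planted_pairs = list(G.planted_pairs) + [
        (new_id, G.sample_ids[s]) for new_id, s in zip(new_ids, src)
    ]
    return out


# ---------------------------------------------------------------------------
# Gene models and GO map
# ---------------------------------------------------------------------------

def _make_genes(config: SimConfig, rng) -> pd.DataFrame:
    spacing = config.genome_length // config.n_genes
    rows = []
    for g in range(config.n_genes):
        length = int(rng.integers(3000, 8000))
        start = g * spacing + int(rng.integers(1, max(2, spacing - length - 1)))
        end = min(start + length, config.genome_length)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(start, end), size=2 * n_exons, replace=False))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons)]
        rows.append(
            {"gene_id": f"gene{g + 1:03d}", "start": start, "end": end,
             "strand": strand, "exons": exons}
        )
    return pd.DataFrame(rows)


def _write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"chr1\tseagea\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons):
                fh.write(
                    f"chr1\tseagea\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i + 1};Parent={g.gene_id}\n"
                )


def _go_map(G: GenotypeMatrix, truth: pd.DataFrame, genes: pd.DataFrame, config: SimConfig, rng):
    """Locus -> gene -> GO-term map.  Genes hosting adaptive loci carry the
    boost term more often, giving the enrichment stage true signal."""
    terms = [f"GO:{1000 + t:07d}" for t in range(config.go_n_terms)]
    gene_terms: dict[str, list[str]] = {}
    adaptive_pos = set(
        G.positions[np.asarray(truth["is_adaptive"], dtype=bool)].tolist()
    )
    for _, g in genes.iterrows():
        k = int(rng.integers(1, 5))
        chosen = list(rng.choice(terms, size=k, replace=False))
        hosts_adaptive = any(g.start <= p <= g.end for p in adaptive_pos)
        p_boost = 0.6 if hosts_adaptive else 0.1
        if rng.random() < p_boost and config.go_boost_term not in chosen:
            chosen.append(config.go_boost_term)
        gene_terms[g.gene_id] = sorted(chosen)
    rows = []
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    for lid, pos in zip(G.locus_ids, G.positions):
        hit = np.flatnonzero((starts <= pos) & (pos <= ends))
        if len(hit):
            gid = genes["gene_id"].iloc[hit[0]]
            rows.append({"locus_id": lid, "gene": gid, "go_terms": ";".join(gene_terms[gid])})
        else:
            rows.append({"locus_id": lid, "gene": "none", "go_terms": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    config: SimConfig
    mask: WaterMask
    sites: pd.DataFrame
    env: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: pd.DataFrame
    paths: dict = field(default_factory=dict)


def write_fixture(
    outdir,
    mask: WaterMask,
    sites: pd.DataFrame,
    env: pd.DataFrame,
    G: GenotypeMatrix,
    truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[dict, GenotypeMatrix]:
    """Write the full file fixture; returns (paths, canonical genotypes).

    Genotypes are re-oriented to the minor allele before writing (planting
    relatives can move a frequency past 0.5), so reading the VCF back with
    :func:`seagea.genoqc.load_genotypes` reproduces the returned matrix
    exactly, including the missingness pattern.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    G = G.copy()
    G.dosage, G.ref, G.alt, _ = _orient_to_minor(G.dosage, G.ref, G.alt)

    paths = {k: outdir / v for k, v in {
        "vcf": "genotypes.vcf",
        "samples": "samples.csv",
        "env": "env.csv",
        "mask": "mask.asc",
        "gff": "genes.gff3",
        "go_map": "go_map.csv",
        "truth": "truth.csv",
    }.items()}

    write_vcf(G, paths["vcf"])
    labels = site_labels(G)
    site_lookup = sites.set_index("site")
    pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "site": labels,
            "lon": [site_lookup.loc[s, "lon"] for s in labels],
            "lat": [site_lookup.loc[s, "lat"] for s in labels],
        }
    ).to_csv(paths["samples"], index=False)
    env.to_csv(paths["env"], index=False)
    write_mask_asc(mask, paths["mask"])
    rng = np.random.default_rng([config.seed, 99])
    genes = _make_genes(config, rng)
    _write_gff3(genes, paths["gff"])
    _go_map(G, truth, genes, config, rng).to_csv(paths["go_map"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}, G


def generate_fixture(config: SimConfig | None = None, outdir=None) -> Fixture:
    """End-to-end convenience: seascape -> genotypes -> planted relatives
    (-> files when ``outdir`` is given)."""
    config = config or SimConfig()
    mask, sites, env = make_seascape(config)
    G, truth = simulate_genotypes(sites, env, config)
    G = plant_relatives(G, config.n_related_pairs, seed=config.seed,
                        missing_rate=config.missing_rate)
    paths: dict = {}
    if outdir is not None:
        paths, G = write_fixture(outdir, mask, sites, env, G, truth, config)
    return Fixture(config=config, mask=mask, sites=sites, env=env,
                   genotypes=G, truth=truth, paths=paths)
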