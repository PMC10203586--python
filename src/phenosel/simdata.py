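"""Synthetic multi-environment wheat trial generator.

Emulates the structure of a large elite-cross yield trial: a founder pool of
inbred parents crossed into biparental and three-way populations, selfed to
F4 and genotyped as pooled DNA of ~6 sibling plants (fractional "codominant"
dosages); four site-year environments with strong genotype-by-environment
interaction; a modified alpha-lattice layout with unbalanced replication;
and a plot-level panel of ~100 redundant phenomic traits (multispectral and
hyperspectral vegetation indices, visual scores, soil conductivity) in which
the spectral categories carry most of the yield signal.

Everything is driven by a single master seed through named child streams
(see :mod:`phenosel._rng`), so identical seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "GeneticMap",
    "Cross",
    "CrossPlan",
    "MarkerMatrix",
    "Environment",
    "SimTruth",
    "TruthConfig",
    "CategorySpec",
    "TraitPanelConfig",
    "SimConfig",
    "SimDataset",
    "haldane_recomb",
    "simulate_founders",
    "make_cross",
    "bulk_genotype",
    "simulate_population",
    "build_design",
    "full_trial_replication_spec",
    "scaled_replication_spec",
    "adjust_yield",
    "simulate_yield",
    "simulate_traits",
    "simulate_study",
    "default_environments",
    "DEFAULT_ENV_CORR",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# Spearman yield correlations among shared lines between the four trial
# environments (Cam 2016, Dux 2016, Dux 2017, Hinx 2017); used as the default
# between-environment genetic correlation target.
DEFAULT_ENV_CORR = np.array(
    [
        [1.000, 0.389, 0.233, 0.150],
        [0.389, 1.000, 0.275, 0.192],
        [0.233, 0.275, 1.000, 0.352],
        [0.150, 0.192, 0.352, 1.000],
    ]
)


# ---------------------------------------------------------------------------
# genetic map and founders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions on a set of linkage groups (positions in cM)."""

    chromosomes: tuple  # of (chrom id, length_cM)
    marker_chrom: np.ndarray  # per-marker chromosome index
    marker_pos: np.ndarray  # per-marker position, cM

    def __post_init__(self):
        lengths = {i: ln for i, (_, ln) in enumerate(self.chromosomes)}
        for i in range(len(self.chromosomes)):
            pos = self.marker_pos[self.marker_chrom == i]
            if pos.size and (np.any(pos < 0) or np.any(pos > lengths[i])):
                raise ConfigurationError("marker positions outside chromosome")
            if pos.size and np.any(np.diff(pos) < 0):
                raise ConfigurationError("marker positions must be non-decreasing")

    @property
    def n_markers(self) -> int:
        return len(self.marker_pos)

    def marker_ids(self) -> list:
        return [
            f"M{self.chromosomes[c][0]}_{i:05d}"
            for i, c in enumerate(self.marker_chrom)
        ]

    @classmethod
    def uniform(cls, n_markers: int, n_chrom: int = 21, chrom_length_cM: float = 150.0):
        """Wheat-like default: markers evenly spread over equal chromosomes."""
        chroms = tuple((f"{i + 1}", float(chrom_length_cM)) for i in range(n_chrom))
        per = np.array_split(np.arange(n_markers), n_chrom)
        chrom_idx = np.concatenate(
            [np.full(len(ix), c, dtype=int) for c, ix in enumerate(per)]
        )
        pos = np.concatenate(
            [np.linspace(0.0, chrom_length_cM, len(ix)) for ix in per if len(ix)]
        )
        return cls(chroms, chrom_idx, pos)

    def _recomb_fractions(self) -> np.ndarray:
        """Per-marker probability of switching parental haplotype relative to
        the previous marker; 0.5 at each chromosome start (independent
        assortment between linkage groups)."""
        rec = np.empty(self.n_markers)
        for c in range(len(self.chromosomes)):
            sel = np.flatnonzero(self.marker_chrom == c)
            if sel.size == 0:
                continue
            rec[sel[0]] = 0.5
            if sel.size > 1:
                d = np.diff(self.marker_pos[sel])
                rec[sel[1:]] = haldane_recomb(d)
        return rec


def haldane_recomb(distance_cM):
    """Recombination fraction for a map distance under the Haldane map
    function (no interference): r = (1 - exp(-2d)) / 2 with d in Morgans."""
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(distance_cM) else r


@dataclass
class MarkerMatrix:
    """Lines x markers dosage table (values in [0, 2], NaN = missing)."""

    dosages: pd.DataFrame
    map: GeneticMap | None = None

    def __post_init__(self):
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 2)):
                raise ValueError("dosages must lie in [0, 2] (or be missing)")
        if self.dosages.index.has_duplicates or self.dosages.columns.has_duplicates:
            raise ValueError("line and marker ids must be unique")

    @property
    def line_ids(self):
        return list(self.dosages.index)

    @property
    def marker_ids(self):
        return list(self.dosages.columns)

    @property
    def shape(self):
        return self.dosages.shape

    def values(self) -> np.ndarray:
        return self.dosages.to_numpy(dtype=float)


def simulate_founders(
    n_parents: int,
    gmap: GeneticMap,
    maf_low: float = 0.2,
    maf_high: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> MarkerMatrix:
    """Fully homozygous founder lines (dosage 0 or 2 per marker).

    Per-marker allele frequency is drawn uniformly in [maf_low, maf_high];
    founder alleles are then independent Bernoulli draws, as for an elite
    pool without explicit pedigree structure.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ConfigurationError("need 0 < maf_low <= maf_high <= 0.5")
    if n_parents < 2:
        raise ConfigurationError("need at least two parents")
    rng = rng if rng is not None else child_rng(seed or 0, "founders")
    p = rng.uniform(maf_low, maf_high, size=gmap.n_markers)
    alleles = (rng.random((n_parents, gmap.n_markers)) < p).astype(float)
    dos = pd.DataFrame(
        2.0 * alleles,
        index=[f"P{i + 1:02d}" for i in range(n_parents)],
        columns=gmap.marker_ids(),
    )
    return MarkerMatrix(dos, gmap)


# ---------------------------------------------------------------------------
# crossing and bulk genotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cross:
    id: str
    parents: tuple  # 2 or 3 parent line ids
    n_lines: int

    def __post_init__(self):
        if len(self.parents) not in (2, 3):
            raise ConfigurationError("cross arity must be 2 or 3")
        if self.n_lines < 1:
            raise ConfigurationError("n_lines must be >= 1")


@dataclass(frozen=True)
class CrossPlan:
    crosses: tuple
    parent_pool: tuple

    def __post_init__(self):
        pool = set(self.parent_pool)
        for c in self.crosses:
            if not set(c.parents) <= pool:
                raise ConfigurationError(f"cross {c.id} uses unknown parents")

    @property
    def n_lines(self) -> int:
        return sum(c.n_lines for c in self.crosses)

    def line_ids(self) -> list:
        return [
            f"{c.id}_L{i + 1:03d}" for c in self.crosses for i in range(c.n_lines)
        ]

    @classmethod
    def random(
        cls,
        parent_ids,
        n_biparental: int,
        n_threeway: int,
        lines_per_cross: int,
        rng: np.random.Generator,
    ) -> "CrossPlan":
        """Random plan over a founder pool; arities mirror a mixed programme
        of biparental and three-way elite crosses."""
        crosses = []
        k = 0
        for arity, n in ((2, n_biparental), (3, n_threeway)):
            for _ in range(n):
                k += 1
                parents = tuple(rng.choice(parent_ids, size=arity, replace=False))
                crosses.append(Cross(f"C{k:02d}", parents, lines_per_cross))
        return cls(tuple(crosses), tuple(parent_ids))


def _gamete(h1: np.ndarray, h2: np.ndarray, rec: np.ndarray, rng) -> np.ndarray:
    """One meiotic product. ``rec`` holds per-marker switch probabilities
    (0.5 at chromosome starts), so crossovers follow the Haldane model."""
    switch = rng.random(rec.size) < rec
    state = np.cumsum(switch) % 2  # 0 -> h1, 1 -> h2
    return np.where(state == 0, h1, h2)


def _self(plant, rec, rng):
    return (_gamete(*plant, rec, rng), _gamete(*plant, rec, rng))


def bulk_genotype(
    plant_dosages: np.ndarray,
    call_error: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pooled-DNA codominant score for one line: the plain mean dosage over
    the sampled sibling plants (rows), giving fractional values in [0, 2].

    ``call_error`` is the per-plant, per-marker probability that a genotype
    call is replaced by a uniform random call in {0, 1, 2}, emulating the
    relaxed array-QC thresholds needed for bulked early-generation material.
    """
    plant_dosages = np.atleast_2d(np.asarray(plant_dosages, dtype=float))
    if plant_dosages.shape[0] < 1:
        raise ConfigurationError("need at least one plant in the pool")
    if call_error:
        if rng is None:
            raise ConfigurationError("call_error > 0 requires an rng")
        flip = rng.random(plant_dosages.shape) < call_error
        noise = rng.integers(0, 3, size=plant_dosages.shape).astype(float)
        plant_dosages = np.where(flip, noise, plant_dosages)
    return plant_dosages.mean(axis=0)


def make_cross(
    parents: np.ndarray,
    n_lines: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    n_plants: int = 6,
    call_error: float = 0.0,
) -> np.ndarray:
    """Simulate one F2:4 population from 2 or 3 homozygous parents.

    Biparental: F1 = P1 x P2, selfed to F2; each line descends from one F2
    plant whose ``n_plants`` F4 descendants (two further selfing meioses,
    no interference) are pooled by :func:`bulk_genotype`. Three-way crosses
    take (P1 x P2) F1 crossed to P3 as the F1-equivalent plant.

    Returns an (n_lines, n_markers) array of pooled dosages.
    """
    parents = np.asarray(parents, dtype=float)
    if parents.ndim != 2 or parents.shape[0] not in (2, 3):
        raise ValueError("expected 2 or 3 parent dosage rows")
    if not np.all(np.isin(parents, (0.0, 2.0))):
        raise ValueError("founders must be homozygous (dosages 0 or 2)")
    rec = gmap._recomb_fractions()
    haps = parents / 2.0
    out = np.empty((n_lines, gmap.n_markers))
    for i in range(n_lines):
        if parents.shape[0] == 2:
            f1 = (haps[0], haps[1])
        else:
            f1 = (_gamete(haps[0], haps[1], rec, rng), haps[2])
        f2 = _self(f1, rec, rng)
        plants = np.empty((n_plants, gmap.n_markers))
        for j in range(n_plants):
            f3 = _self(f2, rec, rng)
            f4 = _self(f3, rec, rng)
            plants[j] = f4[0] + f4[1]
        out[i] = bulk_genotype(plants, call_error=call_error, rng=rng)
    return out


def simulate_population(
    plan: CrossPlan,
    founders: MarkerMatrix,
    rng: np.random.Generator,
    n_plants: int = 6,
    call_error: float = 0.0,
    missing_rate: float = 0.0,
) -> MarkerMatrix:
    """All cross populations of a plan, as one pooled-dosage MarkerMatrix."""
    gmap = founders.map
    blocks = []
    for c in plan.crosses:
        par = founders.dosages.loc[list(c.parents)].to_numpy()
        blocks.append(make_cross(par, c.n_lines, gmap, rng, n_plants, call_error))
    dos = np.vstack(blocks)
    if missing_rate:
        mask = rng.random(dos.shape) < missing_rate
        dos = np.where(mask, np.nan, dos)
    df = pd.DataFrame(dos, index=plan.line_ids(), columns=founders.marker_ids)
    return MarkerMatrix(df, gmap)


# ---------------------------------------------------------------------------
# environments and trial design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Environment:
    """One site-year trial environment."""

    id: str
    year: str
    location: str
    mean_yield: float  # t/ha at 85% dry matter
    latent: tuple = ()  # unitless drivers of GxE / trait expression


def default_environments() -> list:
    """Two locations x two years with distinct yield levels (the second-year
    second site is the low-yielding, drought-affected one)."""
    return [
        Environment("Cam2016", "2016", "Cambridge", 9.5),
        Environment("Dux2016", "2016", "Duxford", 11.0),
        Environment("Dux2017", "2017", "Duxford", 9.8),
        Environment("Hinx2017", "2017", "Hinxton", 7.5),
    ]


def full_trial_replication_spec(env_ids=None) -> pd.DataFrame:
    """Per-line replicate counts by environment for the full trial: six
    groups of lines whose plots sum to 4 across the four environments and to
    2,992 plots within each environment."""
    env_ids = env_ids or ["Cam2016", "Dux2016", "Dux2017", "Hinx2017"]
    rows = [
        (367, 2, 1, 1, 0),
        (381, 2, 1, 0, 1),
        (381, 1, 2, 1, 0),
        (367, 1, 2, 0, 1),
        (748, 1, 1, 1, 1),
        (748, 0, 0, 2, 2),
    ]
    return pd.DataFrame(rows, columns=["n_lines", *env_ids])


def scaled_replication_spec(n_lines: int, env_ids) -> pd.DataFrame:
    """Replication spec with the full trial's unbalanced group proportions,
    rescaled to ``n_lines`` (4 environments) or collapsed to one replicate
    everywhere (other environment counts)."""
    if len(env_ids) != 4:
        rows = [(n_lines, *([1] * len(env_ids)))]
        return pd.DataFrame(rows, columns=["n_lines", *env_ids])
    full = full_trial_replication_spec(env_ids)
    frac = full["n_lines"] / full["n_lines"].sum()
    counts = np.floor(frac * n_lines).astype(int).to_numpy()
    counts[-1] += n_lines - counts.sum()
    spec = full.copy()
    spec["n_lines"] = counts
    return spec[spec["n_lines"] > 0].reset_index(drop=True)


def build_design(
    line_ids,
    env_ids,
    replication_spec: pd.DataFrame,
    rng: np.random.Generator,
    core_subblock: int = 5,
    check_lines=(),
) -> pd.DataFrame:
    """Lay lines into a modified alpha-lattice per environment.

    Lines are allocated to the replication groups in their listed order (so
    cross populations, which are contiguous, fall into groups together, as
    in the real allocation by population). Within an environment, entries
    replicated twice form the alpha-lattice core: they appear once in each
    of two blocks, in randomised sub-blocks of ``core_subblock`` entries.
    Un-replicated entries are split between the blocks and appended randomly
    to the sub-blocks, bringing sub-blocks to roughly double size. Check
    varieties join the replicated core and are flagged.

    Returns the plot table skeleton: one row per plot with columns
    (plot_id, env, block, sub_block, line, is_check).
    """
    env_ids = list(env_ids)
    spec_envs = [c for c in replication_spec.columns if c != "n_lines"]
    if set(spec_envs) != set(env_ids):
        raise ConfigurationError("replication spec environments do not match")
    if int(replication_spec["n_lines"].sum()) != len(line_ids):
        raise ConfigurationError(
            "replication spec line counts must sum to the number of lines"
        )
    # per-line replicate count per environment
    reps = {}
    start = 0
    for _, row in replication_spec.iterrows():
        group = list(line_ids)[start : start + int(row["n_lines"])]
        start += int(row["n_lines"])
        for ln in group:
            reps[ln] = {e: int(row[e]) for e in env_ids}
    records = []
    for env in env_ids:
        core = [ln for ln in line_ids if reps[ln][env] >= 2]
        single = [ln for ln in line_ids if reps[ln][env] == 1]
        core_all = list(core) + list(check_lines)
        n_blocks = 2 if (core_all or len(single) > 8) else 1
        # split un-replicated entries across blocks
        single = list(rng.permutation(single))
        per_block_single = np.array_split(single, n_blocks)
        for b in range(n_blocks):
            entries_core = list(rng.permutation(core_all))
            n_sub = max(1, int(np.ceil(len(entries_core) / core_subblock))) if entries_core else max(
                1, int(np.ceil(len(per_block_single[b]) / (2 * core_subblock)))
            )
            subs = [list(x) for x in np.array_split(entries_core, n_sub)]
            # append un-replicated entries round-robin in random order
            extras = per_block_single[b]
            for k, ln in enumerate(extras):
                subs[k % n_sub].append(ln)
            for s, entries in enumerate(subs):
                for ln in rng.permutation(entries):
                    records.append(
                        (
                            env,
                            f"B{b + 1}",
                            f"B{b + 1}S{s + 1:03d}",
                            ln,
                            ln in check_lines,
                        )
                    )
    design = pd.DataFrame(
        records, columns=["env", "block", "sub_block", "line", "is_check"]
    )
    design.insert(
        0,
        "plot_id",
        [f"{e}_P{i:05d}" for i, e in enumerate(design["env"], start=1)],
    )
    return design


def adjust_yield(raw_yield, moisture_pct):
    """Adjust combine yield to 85% dry matter from measured grain moisture:
    adjusted = raw * (100 - moisture) / 85."""
    m = np.asarray(moisture_pct, dtype=float)
    if np.any((m < 0) | (m > 100)):
        raise ValueError("moisture must be in [0, 100] percent")
    out = np.asarray(raw_yield, dtype=float) * (100.0 - m) / 85.0
    return float(out) if np.isscalar(raw_yield) else out


# ---------------------------------------------------------------------------
# yield with GxE
# ---------------------------------------------------------------------------


@dataclass
class TruthConfig:
    """Ground-truth parameters for the yield model.

    h2 is the plot-level fraction of yield variance (about the environment
    mean) that is genetic; marker_share is the fraction of genetic variance
    tracked by the simulated markers (the rest is polygenic background the
    assay cannot see). env_corr is the between-environment genetic
    correlation matrix (scalar = common off-diagonal value).
    """

    n_qtl: int = 100
    h2: float | dict = 0.4
    env_corr: float | np.ndarray = 0.3
    marker_share: float = 0.7
    sigma_block: float = 0.3
    sigma_subblock: float = 0.2
    sigma_resid: float = 0.35  # plot-condition residual, visible to canopy traits
    sigma_meas: float = 0.5  # harvest measurement error, invisible to traits
    moisture_mean: float = 14.0
    moisture_sd: float = 1.0


@dataclass
class SimTruth:
    """Everything the generator knows that an analyst would not."""

    genetic_values: pd.DataFrame  # lines x envs, t/ha deviation
    marker_effects: pd.DataFrame  # qtl x envs
    h2: dict
    env_corr: pd.DataFrame
    block_effects: dict
    subblock_effects: dict
    trait_loadings: pd.DataFrame | None = None


def _corr_matrix(env_corr, n_env: int) -> np.ndarray:
    if np.isscalar(env_corr):
        R = np.full((n_env, n_env), float(env_corr))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(env_corr, dtype=float)
    if R.shape != (n_env, n_env) or not np.allclose(R, R.T):
        raise ConfigurationError("env_corr must be a symmetric n_env x n_env matrix")
    if not np.allclose(np.diag(R), 1.0):
        raise ConfigurationError("env_corr must have unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-8:
        raise ConfigurationError("env_corr must be positive semi-definite")
    return R


def _corr_transform(R: np.ndarray) -> np.ndarray:
    """Square root usable for singular PSD matrices (e.g. rho = 1)."""
    w, V = np.linalg.eigh(R)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _standardize_cols(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (A - A.mean(axis=0)) / sd


def _recolor(A: np.ndarray, L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whiten columns of A (sample covariance) and recolour with L, so the
    recoloured sample covariance equals L L' exactly. Returns the
    recoloured matrix and the combined linear transform T (A_star = A T')."""
    Ac = A - A.mean(axis=0)
    S = Ac.T @ Ac / Ac.shape[0]
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 1e-12 * max(w.max(), 1e-30), None)
    Wh = V @ np.diag(1.0 / np.sqrt(w)) @ V.T  # symmetric whitener
    T = L @ Wh
    return Ac @ T.T, T


def simulate_yield(
    genotypes: MarkerMatrix,
    envs,
    design: pd.DataFrame,
    truth: TruthConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate plot yields over the design.

    Genetic values per line per environment are built so that their
    between-environment correlations match ``truth.env_corr``: a marker-driven
    component (QTL effects correlated across environments) carries
    ``marker_share`` of the genetic variance and an untyped polygenic
    component, with the same correlation structure, carries the rest.
    Plot yield = environment mean + genetic value + block + sub-block +
    residual; grain moisture is drawn per plot and the stored raw yield
    back-computed so that adjust_yield() recovers the 85%-dry-matter value.
    """
    env_ids = [e.id for e in envs]
    n_env = len(envs)
    lines = genotypes.line_ids
    n = len(lines)
    R = _corr_matrix(truth.env_corr, n_env)
    L = _corr_transform(R)
    h2 = truth.h2 if isinstance(truth.h2, dict) else {e: float(truth.h2) for e in env_ids}
    nuisance_var = (
        truth.sigma_block**2
        + truth.sigma_subblock**2
        + truth.sigma_resid**2
        + truth.sigma_meas**2
    )

    # marker-driven genetic component: QTL effects drawn, then the realized
    # line values whitened and recoloured so the sample correlation matrix
    # across environments equals R exactly (raw Z B correlations are very
    # noisy because cross populations give Z low effective rank)
    Zfull = genotypes.values()
    col_mean = np.nanmean(Zfull, axis=0)
    Zfull = np.where(np.isnan(Zfull), col_mean, Zfull) - col_mean
    n_qtl = min(truth.n_qtl, Zfull.shape[1])
    qtl_idx = rng.choice(Zfull.shape[1], size=n_qtl, replace=False)
    B = rng.standard_normal((n_qtl, n_env)) @ L.T
    A = Zfull[:, qtl_idx] @ B
    W = rng.standard_normal((n, n_env))
    # untyped polygenic part, orthogonalised against the marker part so the
    # mixture's correlation structure is not diluted
    W = W - A @ np.linalg.lstsq(A, W, rcond=None)[0]
    A_star, T_A = _recolor(A, L)
    W_star, _ = _recolor(W, L)
    m = float(truth.marker_share)
    if not 0.0 <= m <= 1.0:
        raise ConfigurationError("marker_share must be in [0, 1]")
    G = np.sqrt(m) * A_star + np.sqrt(1.0 - m) * W_star
    B = B @ T_A.T  # effective marker effects after recolouring
    for j, e in enumerate(env_ids):
        if not 0.0 <= h2[e] < 1.0:
            raise ConfigurationError("h2 must be in [0, 1)")
        sg = np.sqrt(h2[e] / (1.0 - h2[e]) * nuisance_var)
        G[:, j] *= sg
    gvals = pd.DataFrame(G, index=lines, columns=env_ids)

    # design effects
    block_eff = {}
    sub_eff = {}
    for env in env_ids:
        sub = design[design["env"] == env]
        for b in sub["block"].unique():
            block_eff[(env, b)] = rng.normal(0.0, truth.sigma_block)
        for s in sub["sub_block"].unique():
            sub_eff[(env, s)] = rng.normal(0.0, truth.sigma_subblock)

    env_mean = {e.id: e.mean_yield for e in envs}
    plots = design.copy()
    g_plot = gvals.to_numpy()[
        gvals.index.get_indexer(plots["line"]), [env_ids.index(e) for e in plots["env"]]
    ]
    b_plot = np.array([block_eff[(e, b)] for e, b in zip(plots["env"], plots["block"])])
    s_plot = np.array(
        [sub_eff[(e, s)] for e, s in zip(plots["env"], plots["sub_block"])]
    )
    cond = rng.normal(0.0, truth.sigma_resid, size=len(plots))
    meas = rng.normal(0.0, truth.sigma_meas, size=len(plots))
    adj = (
        np.array([env_mean[e] for e in plots["env"]])
        + g_plot + b_plot + s_plot + cond + meas
    )
    adj = np.clip(adj, 0.0, None)
    moisture = np.clip(
        rng.normal(truth.moisture_mean, truth.moisture_sd, size=len(plots)), 5.0, 40.0
    )
    plots["moisture_pct"] = moisture
    plots["raw_yield"] = adj * 85.0 / (100.0 - moisture)
    plots["yield_t_ha"] = adjust_yield(plots["raw_yield"].to_numpy(), moisture)
    plots["genetic_value"] = g_plot
    plots["plot_condition"] = cond
    plots["meas_error"] = meas

    truth_out = SimTruth(
        genetic_values=gvals,
        marker_effects=pd.DataFrame(
            B, index=[genotypes.marker_ids[i] for i in qtl_idx], columns=env_ids
        ),
        h2=h2,
        env_corr=pd.DataFrame(R, index=env_ids, columns=env_ids),
        block_effects=block_eff,
        subblock_effects=sub_eff,
    )
    return plots, truth_out


# ---------------------------------------------------------------------------
# phenomic trait panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySpec:
    """One trait category: how many redundancy groups, how many near-copies
    per group, which time points the groups cycle over, and how much of the
    plot-level yield signal each time point's latent carries."""

    name: str
    n_groups: int
    traits_per_group: int
    time_points: tuple
    signal_share: dict | float  # per time point, fraction of latent variance
    scale: float = 1.0
    offset: float = 0.0

    def share(self, tp: str) -> float:
        if isinstance(self.signal_share, dict):
            return float(self.signal_share[tp])
        return float(self.signal_share)


@dataclass
class TraitPanelConfig:
    categories: tuple
    within_loading: float = 0.97  # squared-loading of traits on their group latent
    trait_noise_sd: float = 1.0

    @classmethod
    def default(cls) -> "TraitPanelConfig":
        """~110 traits in ~40 redundancy groups. Multispectral flights F1-F5
        rise in yield signal to mid grain-fill then fall with senescence;
        hyperspectral (single post-flowering flight) is comparably strong;
        visual scores and soil conductivity carry almost none."""
        ms_share = {"F1": 0.25, "F2": 0.45, "F3": 0.60, "F4": 0.55, "F5": 0.30}
        return cls(
            categories=(
                CategorySpec("multispectral", 15, 3, ("F1", "F2", "F3", "F4", "F5"),
                             ms_share, scale=0.1, offset=0.7),
                CategorySpec("hyperspectral", 18, 3, ("F3",), 0.60, scale=0.2, offset=0.5),
                CategorySpec("visual", 5, 2, ("EARLY", "MID", "LATE"), 0.05,
                             scale=2.0, offset=5.0),
                CategorySpec("soil", 2, 1, ("EARLY",), 0.0, scale=8.0, offset=30.0),
            )
        )

    @classmethod
    def tiny(cls) -> "TraitPanelConfig":
        return cls(
            categories=(
                CategorySpec("multispectral", 4, 2, ("F1", "F3"), {"F1": 0.3, "F3": 0.6}),
                CategorySpec("hyperspectral", 4, 2, ("F3",), 0.6),
                CategorySpec("visual", 2, 1, ("MID",), 0.05),
                CategorySpec("soil", 1, 1, ("EARLY",), 0.0),
            )
        )

    @property
    def n_groups(self) -> int:
        return sum(c.n_groups for c in self.categories)

    @property
    def n_traits(self) -> int:
        return sum(c.n_groups * c.traits_per_group for c in self.categories)


def simulate_traits(
    plots: pd.DataFrame,
    panel_config: TraitPanelConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate plot-level phenomic traits over a simulated plot table.

    Each redundancy group has one latent crop-status variable: a mixture of
    the plot's yield signal (yield minus the environment mean, standardised
    within environment) and group-specific noise, weighted by the category's
    per-time-point signal share. Traits within a group are near-copies of
    the latent (loading^2 = ``within_loading``) plus independent noise, so
    correlation pruning at 0.9 collapses the panel to about one trait per
    group. Values are affine-mapped to category-plausible scales.

    Returns (trait value DataFrame indexed like ``plots``, trait panel).
    """
    if panel_config.trait_noise_sd < 0:
        raise ConfigurationError("trait noise SD must be non-negative")
    # plot-level crop-status signal, standardised within environment; the
    # harvest measurement error is not visible to canopy sensors
    signal = np.empty(len(plots))
    y = plots["yield_t_ha"].to_numpy()
    if "meas_error" in plots:
        y = y - plots["meas_error"].to_numpy()
    for env in plots["env"].unique():
        sel = (plots["env"] == env).to_numpy()
        dev = y[sel] - y[sel].mean()
        sd = dev.std() or 1.0
        signal[sel] = dev / sd
    n = len(plots)
    l2 = float(panel_config.within_loading)
    cols, panel_rows = {}, []
    for cat in panel_config.categories:
        for g in range(cat.n_groups):
            tp = cat.time_points[g % len(cat.time_points)]
            s = cat.share(tp)
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError("signal share must be in [0, 1]")
            latent = np.sqrt(s) * signal + np.sqrt(1.0 - s) * rng.standard_normal(n)
            for t in range(cat.traits_per_group):
                tid = f"{cat.name[:2].upper()}_{tp}_G{g + 1:02d}_T{t + 1}"
                val = np.sqrt(l2) * latent + np.sqrt(1.0 - l2) * (
                    panel_config.trait_noise_sd * rng.standard_normal(n)
                )
                cols[tid] = cat.offset + cat.scale * val
                panel_rows.append(
                    (tid, cat.name, tp, f"{cat.name}_G{g + 1:02d}", s, l2)
                )
    traits = pd.DataFrame(cols, index=plots.index)
    panel = pd.DataFrame(
        panel_rows,
        columns=["trait_id", "category", "time_point", "group",
                 "signal_share", "within_loading"],
    )
    return traits, panel


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Complete specification of one synthetic study."""

    n_parents: int = 27
    n_biparental: int = 8
    n_threeway: int = 2
    lines_per_cross: int = 32
    n_markers: int = 300
    n_chrom: int = 21
    chrom_length_cM: float = 150.0
    maf_low: float = 0.2
    maf_high: float = 0.5
    n_plants_bulk: int = 6
    call_error: float = 0.02
    missing_rate: float = 0.02
    environments: list = field(default_factory=default_environments)
    truth: TruthConfig = field(default_factory=TruthConfig)
    panel: TraitPanelConfig = field(default_factory=TraitPanelConfig.default)
    replication: pd.DataFrame | None = None  # default: scaled full-trial spec
    n_checks: int = 0

    @classmethod
    def tiny(cls) -> "SimConfig":
        """Unit-test scale: 4 crosses x 10 lines, 50 markers, 2 environments."""
        return cls(
            n_parents=8,
            n_biparental=3,
            n_threeway=1,
            lines_per_cross=10,
            n_markers=50,
            n_chrom=5,
            environments=default_environments()[:2],
            truth=TruthConfig(n_qtl=20, env_corr=0.3),
            panel=TraitPanelConfig.tiny(),
        )

    @classmethod
    def demo(cls) -> "SimConfig":
        """Desk-scale default: 10 crosses x 32 lines = 320 lines, 300
        markers, four environments with the full trial's unbalanced
        replication pattern and between-environment correlation targets."""
        return cls(truth=TruthConfig(n_qtl=100, env_corr=DEFAULT_ENV_CORR))

    @classmethod
    def full_scale(cls) -> "SimConfig":
        """Full trial shape: 44 crosses x 68 lines = 2,992 lines over four
        environments (markers kept at desk scale)."""
        return cls(
            n_biparental=39,
            n_threeway=5,
            lines_per_cross=68,
            n_markers=1000,
            truth=TruthConfig(n_qtl=200, env_corr=DEFAULT_ENV_CORR),
        )


@dataclass
class SimDataset:
    """A fully simulated study: everything downstream stages consume."""

    genotypes: MarkerMatrix
    design: pd.DataFrame
    plots: pd.DataFrame  # design + yield + trait columns
    panel: pd.DataFrame
    truth: SimTruth
    environments: list
    config: SimConfig

    @property
    def env_ids(self):
        return [e.id for e in self.environments]

    @property
    def trait_ids(self):
        return list(self.panel["trait_id"])

    @property
    def line_ids(self):
        return self.genotypes.line_ids


def simulate_study(config: SimConfig, seed: int) -> SimDataset:
    """Run the full generator under a master seed: founders, crosses and
    bulk genotyping, trial layout, plot yields with GxE, and the phenomic
    trait panel."""
    gmap = GeneticMap.uniform(config.n_markers, config.n_chrom, config.chrom_length_cM)
    founders = simulate_founders(
        config.n_parents, gmap, config.maf_low, config.maf_high,
        rng=child_rng(seed, "founders"),
    )
    plan = CrossPlan.random(
        founders.line_ids,
        config.n_biparental,
        config.n_threeway,
        config.lines_per_cross,
        child_rng(seed, "crossplan"),
    )
    genotypes = simulate_population(
        plan,
        founders,
        child_rng(seed, "meiosis"),
        n_plants=config.n_plants_bulk,
        call_error=config.call_error,
        missing_rate=config.missing_rate,
    )
    envs = config.environments
    env_ids = [e.id for e in envs]
    replication = (
        config.replication
        if config.replication is not None
        else scaled_replication_spec(plan.n_lines, env_ids)
    )
    design = build_design(
        genotypes.line_ids, env_ids, replication, child_rng(seed, "design")
    )
    plots, truth = simulate_yield(
        genotypes, envs, design, config.truth, child_rng(seed, "yield")
    )
    traits, panel = simulate_traits(plots, config.panel, child_rng(seed, "traits"))
    truth.trait_loadings = panel.set_index("trait_id")[
        ["signal_share", "within_loading"]
    ]
    plots = pd.concat([plots, traits], axis=1)
    return SimDataset(genotypes, design, plots, panel, truth, envs, config)
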