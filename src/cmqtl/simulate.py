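"""Synthetic Diversity-Outbred genomes and a simulated dose-response screen.

The Diversity Outbred (DO) population descends from eight inbred mouse
founder strains; each individual genome is a mosaic of founder haplotypes.
This module generates such mosaics directly as a Markov chain over founders
along each chromosome, emits founder haplotype *dosages* (the 0-2 expected
haplotype counts consumed by the mapping stage), and simulates a well-level
high-content screen: per-individual latent dose-response curves whose
parameters carry a planted QTL, a polygenic term, and covariate shifts, plus
plate / run / residual noise at the well level.

Every downstream stage of the pipeline (curve fitting, batch adjustment,
normalization, genome scanning) can therefore be tested against known ground
truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import ll4

#: Full names of the eight DO founder strains, in the conventional A-H order.
FOUNDER_STRAINS = (
    "A/J",
    "C57BL/6J",
    "129S1/SvImJ",
    "NOD/ShiLtJ",
    "NZO/HILtJ",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
)

#: One-letter founder codes matching :data:`FOUNDER_STRAINS`.
FOUNDER_LETTERS = "ABCDEFGH"

N_FOUNDERS = 8

#: Default cM per Mbp for the synthetic linear genetic map.
DEFAULT_CM_PER_MBP = 0.5


@dataclass(frozen=True)
class MarkerMap:
    """A genotyping grid: marker ids with physical and genetic positions.

    Positions are 1-based bp, strictly increasing within a chromosome; the
    genetic map (cM) is nondecreasing with bp.
    """

    df: pd.DataFrame  # columns: marker_id, chromosome, position_bp, position_cm

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position_bp", "position_cm"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if self.df["marker_id"].duplicated().any():
            raise ValueError("marker_ids must be unique")
        for chrom, sub in self.df.groupby("chromosome", sort=False):
            bp = sub["position_bp"].to_numpy()
            cm = sub["position_cm"].to_numpy()
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"cM not nondecreasing on chromosome {chrom}")
            if (bp <= 0).any() or (cm < 0).any():
                raise ValueError("positions must be positive bp / nonnegative cM")

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list:
        return list(self.df["chromosome"].unique())

    def chrom_index(self, chromosome) -> np.ndarray:
        """Integer marker indices belonging to one chromosome."""
        return np.flatnonzero((self.df["chromosome"] == chromosome).to_numpy())

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero((self.df["marker_id"] == marker_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"marker {marker_id!r} not in map")
        return int(idx[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MarkerMap":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class FounderMosaic:
    """One individual's genome as founder-haplotype segments.

    ``gametes[chromosome]`` holds two tracks, each a list of
    ``(founder_index, start_bp, end_bp)`` segments tiling the chromosome
    (closed 1-based intervals, no gaps or overlaps).
    """

    individual_id: str
    gametes: dict  # chromosome -> (track0, track1), each a list of (founder, start, end)


@dataclass
class GenoProbs:
    """Founder haplotype dosages: individuals x 8 founders x markers.

    At every individual x marker the eight dosages sum to 2 (two gametes).
    """

    dosage: np.ndarray
    individual_ids: list
    marker_map: MarkerMap
    founder_order: tuple = FOUNDER_STRAINS

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 3 or self.dosage.shape[1] != N_FOUNDERS:
            raise ValueError("dosage must be (individuals, 8, markers)")
        if self.dosage.shape[0] != len(self.individual_ids):
            raise ValueError("individual_ids length mismatch")
        if self.dosage.shape[2] != self.marker_map.n_markers:
            raise ValueError("marker count mismatch with map")
        if (self.dosage < 0).any():
            raise ValueError("dosages must be nonnegative")
        sums = self.dosage.sum(axis=1)
        if not np.allclose(sums, 2.0, atol=1e-8):
            bad = np.argwhere(np.abs(sums - 2.0) > 1e-8)[0]
            raise ValueError(
                f"founder dosages must sum to 2; first violation at individual "
                f"{self.individual_ids[bad[0]]}, marker index {bad[1]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[2]


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: which latent curve parameter it moves, where, and how much.

    ``target_trait`` is one of ``log_EC50``, ``slope``, ``lower_asymptote``,
    ``upper_asymptote``. ``founder_effects`` is a centered 8-vector on the
    latent-parameter scale; only its *pattern* matters because the realized
    additive values are rescaled so the locus explains exactly ``h2_qtl`` of
    the latent phenotypic variance.
    """

    target_trait: str
    marker_id: str
    founder_effects: tuple
    h2_qtl: float

    def __post_init__(self) -> None:
        eff = np.asarray(self.founder_effects, dtype=float)
        if eff.shape != (N_FOUNDERS,):
            raise ValueError("founder_effects must have length 8")
        if abs(eff.mean()) > 1e-8:
            raise ValueError("founder_effects must be centered (mean 0)")
        if not 0.0 <= self.h2_qtl < 1.0:
            raise ValueError("h2_qtl must be in [0, 1)")


def biallelic_effects(carriers=(0, 1, 2, 3)) -> tuple:
    """A centered biallelic founder-effect pattern (+1 for carriers, -1 otherwise),
    the 4/4 strain-distribution split used in the power analyses."""
    eff = np.full(N_FOUNDERS, -1.0)
    eff[list(carriers)] = 1.0
    return tuple(eff - eff.mean())


@dataclass(frozen=True)
class StudyDesign:
    """Plate layout and noise structure of the screen.

    Defaults mirror the screen design: eight concentrations of the arsenic
    metabolite MMA(III) including a zero-dose control, four technical
    replicate columns per cell line split over a pair of 96-well plates
    (12 columns per plate, doses down the 8 rows, hence 6 lines per plate
    pair), and runs of 12 lines. Noise standard deviations are expressed as
    fractions of the latent curve span |d - c|.
    """

    doses_um: tuple = (0.0, 0.01, 0.1, 0.75, 1.0, 1.25, 2.0, 5.0)
    n_replicate_columns: int = 4
    lines_per_plate_pair: int = 6
    lines_per_run: int = 12
    sd_plate: float = 0.05
    sd_run: float = 0.03
    sd_residual: float = 0.05
    n_generations: int = 3

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses_um, dtype=float)
        if (doses < 0).any() or not np.all(np.diff(doses) > 0):
            raise ValueError("doses must be nonnegative and strictly increasing")
        if int((doses == 0).sum()) != 1:
            raise ValueError("exactly one zero dose required")
        for sd in (self.sd_plate, self.sd_run, self.sd_residual):
            if sd < 0:
                raise ValueError("noise SDs must be nonnegative")

    def plate_of(self, individual_index: int, replicate: int) -> int:
        """Plate id for a replicate column: columns 0-1 on the first plate of
        the pair, 2-3 on the second."""
        pair = individual_index // self.lines_per_plate_pair
        return 2 * pair + (0 if replicate < 2 else 1)

    def run_of(self, individual_index: int) -> int:
        return individual_index // self.lines_per_run

    def sex_of(self, individual_index: int) -> str:
        return "F" if individual_index % 2 == 0 else "M"

    def generation_of(self, individual_index: int) -> str:
        return f"G{individual_index % self.n_generations}"


# ---------------------------------------------------------------------------
# marker map


def simulate_marker_map(
    n_chromosomes: int = 5,
    markers_per_chromosome: int = 200,
    chromosome_length_bp: int = 150_000_000,
    seed: int = 0,
    spacing: str = "random",
    cm_per_mbp: float = DEFAULT_CM_PER_MBP,
) -> MarkerMap:
    """Build a synthetic marker grid with a linear bp->cM map.

    ``spacing='random'`` draws sorted uniform positions; ``'even'`` spaces
    markers evenly. Deterministic given ``seed``.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1 or chromosome_length_bp < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_chromosomes):
        chrom = str(c + 1)
        if spacing == "even":
            pos = np.linspace(1, chromosome_length_bp, markers_per_chromosome)
            pos = np.round(pos).astype(np.int64)
        elif spacing == "random":
            # draw-and-dedupe: collisions are vanishingly rare on Mbp scales
            pos = np.array([], dtype=np.int64)
            while pos.size < markers_per_chromosome:
                extra = rng.integers(
                    1, chromosome_length_bp + 1, size=2 * markers_per_chromosome
                )
                pos = np.unique(np.concatenate([pos, extra]))
            pos = np.sort(rng.choice(pos, size=markers_per_chromosome, replace=False))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        for i, p in enumerate(pos):
            rows.append(
                {
                    "marker_id": f"c{chrom}_m{i}",
                    "chromosome": chrom,
                    "position_bp": int(p),
                    "position_cm": float(p) / 1e6 * cm_per_mbp,
                }
            )
    return MarkerMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# DO genome mosaics


def _simulate_gametes_chrom(
    rng: np.random.Generator, n_gametes: int, cm: np.ndarray, rate_per_cm: float
) -> np.ndarray:
    """Markov chain over 8 founders along one chromosome.

    Uniform start; per marker interval the chain switches with probability
    1 - exp(-rate * dcM) to one of the other 7 founders uniformly. Returns an
    (n_gametes, n_markers) int array of founder indices.
    """
    n_markers = cm.size
    # Refresh construction: jumping to a uniform draw over all 8 founders
    # with probability p * 8/7 changes state with probability p and, given a
    # change, lands uniformly on the other 7 -- the desired kernel -- while
    # letting the whole chain vectorize via a last-refresh scan.
    start = rng.integers(0, N_FOUNDERS, size=n_gametes)
    if n_markers == 1:
        return start[:, None].astype(np.int8)
    p_switch = 1.0 - np.exp(-rate_per_cm * np.diff(cm))
    p_refresh = np.minimum(p_switch * N_FOUNDERS / (N_FOUNDERS - 1), 1.0)
    refresh = rng.random((n_gametes, n_markers - 1)) < p_refresh
    values = np.empty((n_gametes, n_markers), dtype=np.int64)
    values[:, 0] = start
    values[:, 1:] = rng.integers(0, N_FOUNDERS, size=(n_gametes, n_markers - 1))
    idx = np.zeros((n_gametes, n_markers), dtype=np.int64)
    cols = np.broadcast_to(np.arange(1, n_markers), refresh.shape)
    idx[:, 1:] = np.where(refresh, cols, 0)
    last = np.maximum.accumulate(idx, axis=1)
    return values[np.arange(n_gametes)[:, None], last].astype(np.int8)


def _segments_from_states(
    states: np.ndarray, bp: np.ndarray, chrom_end: int
) -> list:
    """Collapse a per-marker founder sequence into bp segments tiling
    [1, chrom_end]; breakpoints at midpoints between flanking markers."""
    segs = []
    start = 1
    for m in range(1, states.size):
        if states[m] != states[m - 1]:
            cut = int((bp[m - 1] + bp[m]) // 2)
            segs.append((int(states[m - 1]), start, cut))
            start = cut + 1
    segs.append((int(states[-1]), start, int(chrom_end)))
    return segs


def simulate_do_genoprobs(
    n_individuals: int,
    marker_map: MarkerMap,
    recomb_rate_per_cm: float = 0.1,
    seed: int = 0,
    blur: float = 0.0,
) -> tuple:
    """Simulate DO-style genomes and return (mosaics, GenoProbs).

    Each individual carries two independent gamete tracks per chromosome,
    each a Markov chain over the 8 founders with switch probability
    ``1 - exp(-rate * dcM)`` per marker interval. Dosages are the indicator
    sum of the two gametes (hard 0/1/2); ``blur`` in [0, 1] mixes dosages
    toward the uniform 1/8 profile to emulate haplotype-reconstruction
    uncertainty while preserving the sum-to-2 invariant.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if recomb_rate_per_cm < 0:
        raise ValueError("recomb rate must be >= 0")
    if not 0.0 <= blur <= 1.0:
        raise ValueError("blur must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"DO{i:04d}" for i in range(n_individuals)]
    n_markers = marker_map.n_markers
    dosage = np.zeros((n_individuals, N_FOUNDERS, n_markers))
    gametes_by_ind = [dict() for _ in range(n_individuals)]
    for chrom in marker_map.chromosomes:
        idx = marker_map.chrom_index(chrom)
        sub = marker_map.df.iloc[idx]
        cm = sub["position_cm"].to_numpy()
        bp = sub["position_bp"].to_numpy()
        states = _simulate_gametes_chrom(rng, 2 * n_individuals, cm, recomb_rate_per_cm)
        g0, g1 = states[0::2], states[1::2]
        for f in range(N_FOUNDERS):
            dosage[:, f, idx] = (g0 == f).astype(float) + (g1 == f).astype(float)
        chrom_end = int(bp[-1])
        for i in range(n_individuals):
            gametes_by_ind[i][chrom] = (
                _segments_from_states(g0[i], bp, chrom_end),
                _segments_from_states(g1[i], bp, chrom_end),
            )
    if blur > 0:
        dosage = (1.0 - blur) * dosage + blur * (2.0 / N_FOUNDERS)
    mosaics = [FounderMosaic(ids[i], gametes_by_ind[i]) for i in range(n_individuals)]
    return mosaics, GenoProbs(dosage, ids, marker_map)


# ---------------------------------------------------------------------------
# screen simulation

_TRAIT_TO_PARAM = {
    "log_EC50": "log_e",
    "slope": "b",
    "lower_asymptote": "c",
    "upper_asymptote": "d",
}

#: Baseline latent curve: decreasing response (b > 0 means the zero-dose
#: limit is the upper asymptote d), inflection at 1 uM, inside the dose grid.
DEFAULT_CURVE = {"b": 1.5, "c": 0.2, "d": 1.0, "log_e": 0.0}

#: Total latent variance of the targeted curve parameter (e.g. var of
#: log-EC50 across individuals). SD 0.3 on log-EC50 spans roughly a
#: 1.8-fold EC50 range across the population.
DEFAULT_LATENT_VARIANCE = 0.09


@dataclass
class SimulatedScreen:
    """Well-level trait values plus the ground-truth sidecar."""

    well_table: pd.DataFrame
    truth: pd.DataFrame  # one row per individual: latent params + components
    design: StudyDesign
    qtl_specs: list
    feature: str


def _scale_to_variance(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale so the realized (population) variance is exact."""
    x = x - x.mean()
    v = x.var()
    if v <= 0:
        if target_var > 0:
            raise ValueError("cannot scale a constant component to positive variance")
        return x
    return x * np.sqrt(target_var / v)


def simulate_screen(
    genoprobs: GenoProbs,
    qtl_specs,
    design: StudyDesign = StudyDesign(),
    polygenic_h2: float = 0.15,
    seed: int = 0,
    feature: str = "cell_area_mean_per_well",
    baseline: dict = None,
    latent_variance: float = DEFAULT_LATENT_VARIANCE,
    sex_effect: float = 0.05,
    generation_effect: float = 0.03,
) -> SimulatedScreen:
    """Simulate a well-level screen for one morphology feature.

    Per individual, the targeted latent curve parameter is
    ``baseline + QTL + polygenic + sex/generation shifts + residual`` where
    the QTL term (founder dosages x centered effects) is rescaled to explain
    exactly ``h2_qtl`` of ``latent_variance``, the polygenic term is drawn
    from N(0, K) (K = overall kinship of the supplied genomes) and rescaled
    to ``polygenic_h2``, and the individual residual takes up the remainder.
    Well values evaluate the four-parameter log-logistic curve at the design
    doses plus plate, run, and residual Gaussian noise.
    """
    qtl_specs = list(qtl_specs)
    h2_qtl_total = sum(s.h2_qtl for s in qtl_specs)
    if h2_qtl_total + polygenic_h2 >= 1.0:
        raise ValueError("variance fractions (QTL + polygenic) must sum to < 1")
    targets = {s.target_trait for s in qtl_specs}
    unknown = targets - set(_TRAIT_TO_PARAM)
    if unknown:
        raise ValueError(f"unknown target traits: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = genoprobs.n_individuals
    base = dict(DEFAULT_CURVE if baseline is None else baseline)

    # latent parameter values per individual, one array per curve parameter
    latent = {p: np.full(n, base[p], dtype=float) for p in ("b", "c", "d", "log_e")}
    truth_cols = {}

    # polygenic covariance from the overall kinship of these genomes
    from .mapping import calc_kinship

    K = calc_kinship(genoprobs, loco=False).overall
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))

    sex_idx = np.array([0 if design.sex_of(i) == "F" else 1 for i in range(n)])
    gen_idx = np.array(
        [int(design.generation_of(i)[1:]) for i in range(n)]
    )

    # group specs by the latent parameter they act on
    for trait, param in _TRAIT_TO_PARAM.items():
        specs = [s for s in qtl_specs if s.target_trait == trait]
        if not specs and trait != "log_EC50":
            continue
        qtl_term = np.zeros(n)
        for s in specs:
            m = genoprobs.marker_map.marker_index(s.marker_id)
            g = genoprobs.dosage[:, :, m] @ np.asarray(s.founder_effects)
            qtl_term += _scale_to_variance(g, s.h2_qtl * latent_variance)
        poly = _scale_to_variance(L @ rng.standard_normal(n), polygenic_h2 * latent_variance)
        h2_here = sum(s.h2_qtl for s in specs)
        resid_var = max(0.0, (1.0 - h2_here - polygenic_h2)) * latent_variance
        resid = rng.standard_normal(n) * np.sqrt(resid_var)
        shifts = sex_effect * (sex_idx - sex_idx.mean()) + generation_effect * (
            gen_idx - gen_idx.mean()
        )
        latent[param] = latent[param] + qtl_term + poly + resid + shifts
        truth_cols[f"{param}_qtl"] = qtl_term
        truth_cols[f"{param}_polygenic"] = poly
        truth_cols[f"{param}_residual"] = resid

    doses = np.asarray(design.doses_um)
    span = abs(base["d"] - base["c"])
    plates = sorted(
        {design.plate_of(i, r) for i in range(n) for r in range(design.n_replicate_columns)}
    )
    runs = sorted({design.run_of(i) for i in range(n)})
    plate_eff = dict(zip(plates, rng.standard_normal(len(plates)) * design.sd_plate * span))
    run_eff = dict(zip(runs, rng.standard_normal(len(runs)) * design.sd_run * span))

    rows = []
    for i, ind in enumerate(genoprobs.individual_ids):
        curve = ll4(
            doses, latent["b"][i], latent["c"][i], latent["d"][i], np.exp(latent["log_e"][i])
        )
        sex, gen, run = design.sex_of(i), design.generation_of(i), design.run_of(i)
        for r in range(design.n_replicate_columns):
            plate = design.plate_of(i, r)
            noise = rng.standard_normal(doses.size) * design.sd_residual * span
            values = curve + plate_eff[plate] + run_eff[run] + noise
            for d_i, dose in enumerate(doses):
                rows.append(
                    (ind, sex, gen, f"P{plate:03d}", f"R{run:03d}", r, dose, feature, values[d_i])
                )
    well_table = pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "sex",
            "generation",
            "plate",
            "run",
            "replicate_column",
            "dose_um",
            "feature",
            "value",
        ],
    )
    truth = pd.DataFrame(
        {
            "individual_id": genoprobs.individual_ids,
            "sex": [design.sex_of(i) for i in range(n)],
            "generation": [design.generation_of(i) for i in range(n)],
            "b": latent["b"],
            "c": latent["c"],
            "d": latent["d"],
            "log_e": latent["log_e"],
            "EC50": np.exp(latent["log_e"]),
            **truth_cols,
        }
    )
    return SimulatedScreen(well_table, truth, design, qtl_specs, feature)
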