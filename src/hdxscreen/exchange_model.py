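"""Forward simulation of hydrogen-deuterium exchange for a screening study.

This module is the pipeline's ground-truth generator.  It forward-simulates
amide exchange kinetics under the classic two-state (EX2) picture: each
non-proline residue *i* exchanges as a single exponential with observed rate

    k_obs,i = k_int,i / P_i

where ``k_int`` is the intrinsic (unstructured) exchange rate and ``P`` the
protection factor contributed by structure.  Ligand binding is modelled as an
additive shift on log10(P) over named structural regions (helices H1..H12, the
beta-sheet region BSR), scaled by fractional occupancy.  Peptide-level
observations are Dmax-normalised %D values: the mean exchanged fraction over
the peptide's exchangeable residues, times 100, plus Gaussian replicate noise.

The default construct emulates a nuclear-receptor ligand-binding domain of
254 residues numbered 265-518, with a fast-exchanging C-terminal activation
helix (H10-H12) and a slower core, probed by ~54 overlapping peptic peptides
covering ~98% of the sequence.  A compound library of three pharmacological
classes is supported: all binders protect the orthosteric pocket (BSR, H3,
H7, weakly H2); agonists additionally stabilise H12/H4/H10 strongly; partial
agonists stabilise H12 weakly; inverse agonists leave H12 untouched.
Functional-assay readouts are linear in a planted regional-stabilisation
score with tunable noise, so structure-activity correlations downstream have
a known population value.

Intrinsic rates are sampled log-uniformly over a physically fast window
(0.1-30 1/s, the regime of unstructured amides near neutral pH) rather than
from sequence-dependent rate tables: the downstream analysis only uses
*relative* protection between conditions, and keeping k_int fast ensures the
observed exchange speed of a region is set by its protection, so the
little-protected activation helix is essentially fully deuterated by the
first timepoint while the protected core spreads across the time course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .uptake import Peptide, exchangeable_positions, exchangeable_residue_count

__all__ = [
    "Region",
    "ProteinModel",
    "CompoundSpec",
    "SimulationConfig",
    "LinkSpec",
    "AssayLinkModel",
    "ScreenStudy",
    "FULL_TIMEPOINTS",
    "SCREEN_TIMEPOINTS",
    "PHARM_CLASSES",
    "ASSAYS",
    "DEFAULT_REGIONS",
    "DEFAULT_CLASS_PROPORTIONS",
    "DEFAULT_EFFECT_SIZES",
    "build_default_protein",
    "simulate_residue_fraction",
    "peptide_percent_d",
    "simulate_peptide_observations",
    "generate_peptide_map",
    "simulate_compound_library",
    "region_score",
    "default_assay_links",
    "simulate_activities",
    "simulate_dataset",
    "simulate_screen_study",
    "perturbed_regions",
    "peptides_overlapping_regions",
]

# 8-point exchange time course (seconds) and the fast two-point screen.
FULL_TIMEPOINTS: tuple[float, ...] = (0.0, 10.0, 30.0, 110.0, 380.0, 1270.0, 4270.0, 14400.0)
SCREEN_TIMEPOINTS: tuple[float, ...] = (10.0, 14400.0)

PHARM_CLASSES = ("agonist", "partial_agonist", "inverse_agonist", "null")
ASSAYS = ("alphascreen", "thermal_shift", "cell_reporter")

# Proline is placed explicitly so exclusion rules get exercised downstream.
_AA_NO_PRO = "ACDEFGHIKLMNQRSTVWY"
_DEUTERIUM_MASS_SHIFT = 1.00628  # Da per incorporated deuteron
_PROTON_MASS = 1.00728


@dataclass(frozen=True)
class Region:
    """A named structural element in construct numbering (inclusive)."""

    name: str
    start: int
    end: int


# Helix/sheet layout of the default 254-residue construct (numbered 265-518).
DEFAULT_FIRST_INDEX = 265
DEFAULT_LENGTH = 254
DEFAULT_REGIONS: tuple[Region, ...] = (
    Region("H1", 270, 288),
    Region("H2", 300, 316),
    Region("H3", 318, 340),
    Region("H4", 342, 355),
    Region("H5", 357, 371),
    Region("BSR", 372, 392),
    Region("H6", 394, 403),
    Region("H7", 405, 424),
    Region("H8", 426, 438),
    Region("H9", 440, 458),
    Region("H10", 461, 479),
    Region("H11", 481, 494),
    Region("H12", 499, 510),
)

# Mean baseline log10 protection per region.  The structured core exchanges
# slowly; the C-terminal activation helix region (H10-H12) exchanges fast,
# i.e. shows little protection in the apo state.  Unassigned residues
# (loops) get the loop mean.  Per-residue values are drawn around these
# means with SD 0.3 and clipped at 0 so P >= 1 always.
_REGION_BASELINE_LOG10P: dict[str, float] = {
    "H1": 1.8,
    "H2": 2.0,
    "H3": 2.2,
    "H4": 2.0,
    "H5": 2.2,
    "BSR": 1.5,
    "H6": 1.8,
    "H7": 2.0,
    "H8": 2.2,
    "H9": 2.2,
    "H10": 0.5,
    "H11": 0.5,
    "H12": 0.4,
}
_LOOP_BASELINE_LOG10P = 1.0
_BASELINE_SD = 0.3

# log10 k_int sampling window (1/s): unstructured amides exchange fast near
# neutral pH; protection, not k_int, sets a region's observed speed.
_LOG10_KINT_RANGE = (-1.0, 1.5)


@dataclass(frozen=True)
class ProteinModel:
    """Residue-level exchange model of one protein construct.

    Parameters
    ----------
    sequence
        Amino-acid string of the construct (may contain prolines).
    first_index
        Construct number of the first residue (e.g. 265).
    regions
        Named structural elements, each within the construct span.
    baseline_log10_protection
        Per-residue log10 protection factor of the apo protein; must be
        >= 0 everywhere (protection never accelerates exchange).
    intrinsic_rate
        Per-residue intrinsic exchange rate ``k_int`` in 1/s; must be > 0.
    """

    sequence: str
    first_index: int
    regions: tuple[Region, ...]
    baseline_log10_protection: np.ndarray
    intrinsic_rate: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sequence)
        base = np.asarray(self.baseline_log10_protection, dtype=float)
        kint = np.asarray(self.intrinsic_rate, dtype=float)
        if base.shape != (n,) or kint.shape != (n,):
            raise ValueError("per-residue arrays must match sequence length")
        if np.any(base < 0):
            raise ValueError("baseline log10 protection must be >= 0 (P >= 1)")
        if np.any(kint <= 0):
            raise ValueError("intrinsic rates must be positive")
        last = self.first_index + n - 1
        for reg in self.regions:
            if reg.start > reg.end or reg.start < self.first_index or reg.end > last:
                raise ValueError(f"region {reg.name} outside construct bounds")
        object.__setattr__(self, "baseline_log10_protection", base)
        object.__setattr__(self, "intrinsic_rate", kint)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def last_index(self) -> int:
        return self.first_index + len(self.sequence) - 1

    def region(self, name: str) -> Region:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise KeyError(f"unknown region {name!r}")

    def region_residues(self, name: str, exclude_proline: bool = True) -> np.ndarray:
        """Construct-numbered residues of a region (prolines excluded by default)."""
        reg = self.region(name)
        res = np.arange(reg.start, reg.end + 1)
        if exclude_proline:
            offs = res - self.first_index
            keep = np.array([self.sequence[o] != "P" for o in offs])
            res = res[keep]
        return res

    def effective_log10_protection(self, compound: "CompoundSpec | None") -> np.ndarray:
        """Per-residue log10 P under a bound compound (baseline if None).

        Region effects are additive on log10 P and scaled by occupancy; the
        result is clipped at 0 so the P >= 1 invariant survives any
        (hypothetical) destabilising effect.
        """
        eff = self.baseline_log10_protection.copy()
        if compound is not None:
            for name, delta in compound.region_effects.items():
                reg = self.region(name)  # KeyError on unknown region
                lo = reg.start - self.first_index
                hi = reg.end - self.first_index + 1
                eff[lo:hi] += compound.occupancy * delta
        return np.clip(eff, 0.0, None)


@dataclass(frozen=True)
class CompoundSpec:
    """A library member: pharmacological class plus planted regional effects.

    ``region_effects`` maps region name -> additive shift on log10 P
    (dimensionless); ``occupancy`` scales all effects (1.0 = saturating
    single-concentration design).
    """

    id: str
    pharm_class: str
    region_effects: Mapping[str, float] = field(default_factory=dict)
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.pharm_class not in PHARM_CLASSES:
            raise ValueError(
                f"unknown pharmacological class {self.pharm_class!r}; "
                f"expected one of {PHARM_CLASSES}"
            )
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.pharm_class == "null" and self.region_effects:
            raise ValueError("null compounds must have empty region_effects")
        object.__setattr__(self, "region_effects", dict(self.region_effects))


@dataclass(frozen=True)
class SimulationConfig:
    """Observation-level settings for simulated HDX experiments.

    ``noise_sd_percent_d`` is the replicate SD in percentage points (1.5 is
    a typical HDX replicate precision).  ``d2o_fraction`` (5 uL sample into
    20 uL D2O buffer -> 0.8) and ``back_exchange_loss`` only matter in raw
    centroid mode; Dmax normalisation cancels them in %D space.
    """

    timepoints: tuple[float, ...] = FULL_TIMEPOINTS
    n_replicates: int = 3
    noise_sd_percent_d: float = 1.5
    d2o_fraction: float = 0.8
    back_exchange_loss: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if any(t < 0 for t in tps):
            raise ValueError("timepoints must be non-negative")
        nonzero = [t for t in tps if t > 0]
        if any(b <= a for a, b in zip(nonzero, nonzero[1:])):
            raise ValueError("timepoints must be strictly increasing after 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd_percent_d < 0:
            raise ValueError("noise SD must be >= 0")
        for name in ("d2o_fraction", "back_exchange_loss"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        object.__setattr__(self, "timepoints", tps)


def screen_config(seed: int = 0, n_replicates: int = 5, **kwargs) -> SimulationConfig:
    """Two-timepoint (10 s / 4 hr) screening configuration, 5 replicates."""
    return SimulationConfig(
        timepoints=SCREEN_TIMEPOINTS, n_replicates=n_replicates, seed=seed, **kwargs
    )


def build_default_protein(
    seed: int = 0,
    length: int = DEFAULT_LENGTH,
    first_index: int = DEFAULT_FIRST_INDEX,
    regions: tuple[Region, ...] = DEFAULT_REGIONS,
    proline_fraction: float = 0.05,
) -> ProteinModel:
    """Synthetic ligand-binding-domain-like construct.

    The sequence is random (prolines placed explicitly at the given
    fraction), baseline protection is drawn per residue around region means
    (fast H10-H12, slow core) and log10 k_int is uniform on [-1, 1.5] 1/s.
    """
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(_AA_NO_PRO), size=length)
    is_pro = rng.random(length) < proline_fraction
    seq = "".join("P" if p else a for a, p in zip(letters, is_pro))

    means = np.full(length, _LOOP_BASELINE_LOG10P)
    for reg in regions:
        lo, hi = reg.start - first_index, reg.end - first_index + 1
        means[lo:hi] = _REGION_BASELINE_LOG10P.get(reg.name, _LOOP_BASELINE_LOG10P)
    baseline = np.clip(means + rng.normal(0.0, _BASELINE_SD, length), 0.0, None)
    kint = 10.0 ** rng.uniform(*_LOG10_KINT_RANGE, length)
    return ProteinModel(
        sequence=seq,
        first_index=first_index,
        regions=tuple(regions),
        baseline_log10_protection=baseline,
        intrinsic_rate=kint,
    )


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def simulate_residue_fraction(
    protein: ProteinModel,
    compound: CompoundSpec | None,
    residue: int,
    t: float,
) -> float:
    """Exchanged fraction of one residue at time ``t`` (Dmax-normalised).

    Single-exponential EX2 kinetics: ``1 - exp(-(k_int / P_eff) * t)`` with
    ``log10 P_eff = baseline + occupancy * sum(region effects covering the
    residue)``.  The fraction is relative to full exchange, so D2O fraction
    and back-exchange cancel and the value lies in [0, 1].
    """
    if t < 0:
        raise ValueError("exchange time must be non-negative")
    if not protein.first_index <= residue <= protein.last_index:
        raise IndexError(
            f"residue {residue} outside construct "
            f"[{protein.first_index}, {protein.last_index}]"
        )
    off = residue - protein.first_index
    log10p = protein.effective_log10_protection(compound)[off]
    k_obs = protein.intrinsic_rate[off] / 10.0**log10p
    return float(-np.expm1(-k_obs * t))


def _fraction_grid(
    protein: ProteinModel,
    compound: CompoundSpec | None,
    timepoints: Sequence[float],
) -> np.ndarray:
    """(n_residues, n_timepoints) exchanged fractions, noise-free."""
    log10p = protein.effective_log10_protection(compound)
    k_obs = protein.intrinsic_rate / 10.0**log10p
    t = np.asarray(timepoints, dtype=float)
    return -np.expm1(-np.outer(k_obs, t))


def peptide_percent_d(
    protein: ProteinModel,
    peptides: Sequence[Peptide],
    compound: CompoundSpec | None,
    timepoints: Sequence[float],
) -> np.ndarray:
    """Noise-free %D, shape (n_peptides, n_timepoints).

    The peptide value is the mean exchanged fraction over its exchangeable
    residues (first two residues and prolines excluded) times 100.
    """
    grid = _fraction_grid(protein, compound, timepoints)
    out = np.empty((len(peptides), grid.shape[1]))
    for j, pep in enumerate(peptides):
        pos = exchangeable_positions(pep)
        if not pos:
            raise ValueError(f"peptide {pep.id!r} has no exchangeable residues")
        idx = np.asarray(pos) - protein.first_index
        if idx.min() < 0 or idx.max() >= len(protein.sequence):
            raise IndexError(f"peptide {pep.id!r} outside construct bounds")
        out[j] = 100.0 * grid[idx].mean(axis=0)
    return out


def _percent_d_to_centroids(
    pct: np.ndarray, peptide: Peptide, config: SimulationConfig
) -> tuple[float, np.ndarray, float]:
    """Map %D values onto (undeuterated, observed, Dmax) centroid m/z."""
    n_ex = exchangeable_residue_count(peptide)
    mass = 110.0 * len(peptide) + 18.0  # coarse average residue mass
    undeut = (mass + peptide.charge * _PROTON_MASS) / peptide.charge
    # Deuterons retained in the Dmax control after labelling and back-exchange.
    retained = n_ex * config.d2o_fraction * (1.0 - config.back_exchange_loss)
    dmax = undeut + retained * _DEUTERIUM_MASS_SHIFT / peptide.charge
    observed = undeut + (pct / 100.0) * (dmax - undeut)
    return undeut, observed, dmax


def simulate_peptide_observations(
    protein: ProteinModel,
    peptide: Peptide,
    compound: CompoundSpec | None,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    raw: bool = False,
) -> pd.DataFrame:
    """Replicate-level observations for one peptide under one condition.

    Returns a tidy frame with ``timepoint_s``, ``replicate`` and either
    ``percent_d`` (default) or centroid columns ``undeut_mz``, ``obs_mz``,
    ``dmax_mz`` (``raw=True``), the latter algebraically consistent with the
    same %D so the uptake formula can be exercised end to end.  Noisy %D is
    clipped to [0, 100]; deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clean = peptide_percent_d(protein, [peptide], compound, config.timepoints)[0]
    rows = []
    for it, t in enumerate(config.timepoints):
        noise = rng.normal(0.0, config.noise_sd_percent_d, config.n_replicates)
        vals = np.clip(clean[it] + noise, 0.0, 100.0)
        for r in range(config.n_replicates):
            rows.append((t, r + 1, vals[r]))
    df = pd.DataFrame(rows, columns=["timepoint_s", "replicate", "percent_d"])
    if raw:
        undeut, obs, dmax = _percent_d_to_centroids(
            df["percent_d"].to_numpy(), peptide, config
        )
        df = df.drop(columns="percent_d").assign(
            undeut_mz=undeut, obs_mz=obs, dmax_mz=dmax
        )
    return df


# ---------------------------------------------------------------------------
# Peptide map
# ---------------------------------------------------------------------------

def generate_peptide_map(
    sequence: str,
    first_index: int = 1,
    target_coverage: float = 0.98,
    mean_length: float = 10.0,
    overlap_depth: float = 2.17,
    n_peptides: int | None = None,
    seed: int = 0,
    max_tries: int = 200,
) -> list[Peptide]:
    """Overlapping peptic-style peptide map with controlled union coverage.

    Coverage (union of full spans over the sequence) lands within two
    percentage points of ``target_coverage``.  When ``n_peptides`` is not
    given it is derived as ``round(covered * overlap_depth / mean_length)``;
    the defaults on a 254-residue construct yield 54 peptides at ~98%
    coverage, i.e. a typical in-line pepsin digestion map.  Raises
    ``ValueError`` if the requested coverage is unreachable with the
    requested peptide count.
    """
    if not 0.0 < target_coverage <= 1.0:
        raise ValueError("target_coverage must lie in (0, 1]")
    if mean_length < 4:
        raise ValueError("mean_length must be >= 4")
    length = len(sequence)
    covered_target = int(round(target_coverage * length))
    if n_peptides is None:
        n_peptides = int(round(covered_target * overlap_depth / mean_length))
    max_len = max(int(mean_length * 1.8), int(mean_length) + 2)
    min_len = 6
    if n_peptides * max_len < covered_target:
        raise ValueError(
            f"coverage unreachable: {n_peptides} peptides of at most "
            f"{max_len} residues cannot cover {covered_target} residues"
        )

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        peptides = _try_peptide_map(
            sequence, first_index, length, covered_target, n_peptides,
            mean_length, min_len, max_len, rng,
        )
        if peptides is not None:
            return peptides
    raise ValueError("could not build a peptide map under the given constraints")


def _try_peptide_map(
    sequence, first_index, length, covered_target, n_peptides,
    mean_length, min_len, max_len, rng,
):
    gap_total = length - covered_target
    # Place uncovered runs in the interior, away from the termini.
    if gap_total == 0:
        blocks = [(0, length)]
    else:
        n_runs = 1 if gap_total <= 6 else 2
        sizes = [gap_total] if n_runs == 1 else [gap_total // 2, gap_total - gap_total // 2]
        starts = sorted(rng.choice(np.arange(20, length - 20 - max(sizes)), n_runs, replace=False))
        if n_runs == 2 and starts[1] - starts[0] < sizes[0] + 25:
            return None
        blocks, prev = [], 0
        for s, sz in zip(starts, sizes):
            blocks.append((prev, s))
            prev = s + sz
        blocks.append((prev, length))
        if any(b - a < 20 for a, b in blocks):
            return None

    # Allocate peptides to blocks proportionally (largest remainder).
    lens = [b - a for a, b in blocks]
    quotas = [n_peptides * L / sum(lens) for L in lens]
    counts = [int(q) for q in quotas]
    rema = sorted(range(len(blocks)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in rema[: n_peptides - sum(counts)]:
        counts[i] += 1
    if any(c < 1 for c in counts):
        return None

    peptides: list[Peptide] = []
    for (a, b), k in zip(blocks, counts):
        tiled = _tile_block(b - a, k, mean_length, min_len, max_len, rng)
        if tiled is None:
            return None
        for s_rel, ln in tiled:
            start = first_index + a + s_rel
            seq = sequence[a + s_rel : a + s_rel + ln]
            charge = int(rng.choice([1, 2, 3], p=[0.2, 0.55, 0.25]))
            pep = Peptide(
                id=f"{start}-{start + ln - 1}({charge})",
                sequence=seq,
                start=start,
                end=start + ln - 1,
                charge=charge,
            )
            if exchangeable_residue_count(pep) < 3:
                return None  # proline-heavy draw; retry the whole map
            peptides.append(pep)
    # Distinct ids (duplicate span+charge draws are possible but useless).
    if len({p.id for p in peptides}) != len(peptides):
        return None
    return peptides


def _tile_block(B, k, mean_length, min_len, max_len, rng):
    """Start/length pairs (0-based within block) tiling [0, B) without gaps."""
    lengths = np.clip(
        np.round(rng.normal(mean_length, 2.0, k)).astype(int), min_len, max_len
    )
    if k == 1:
        if B < min_len or B > max_len:
            return None
        return [(0, B)]
    if lengths.sum() < B + k - 1:
        return None
    span = B - lengths[-1]
    if span <= 0:
        return None
    starts = np.round(np.arange(k) * span / (k - 1)).astype(int)
    starts[1:-1] += rng.integers(-2, 3, max(k - 2, 0))
    starts[0], starts[-1] = 0, span
    starts = np.sort(starts)
    for i in range(1, k):
        lo = starts[i - 1] + 1
        hi = starts[i - 1] + lengths[i - 1]  # keep the union contiguous
        starts[i] = min(max(starts[i], lo), hi, B - lengths[i])
        if starts[i] < lo:
            return None
    if starts[-1] + lengths[-1] != B:
        return None
    return list(zip(starts.tolist(), lengths.tolist()))


# ---------------------------------------------------------------------------
# Compound library and assay links
# ---------------------------------------------------------------------------

# Effect sizes are (mean, sd) of additive shifts on log10 P, truncated at 0.
# Every binder protects the orthosteric pocket (BSR/H3/H7) and weakly H2;
# classes differ in the activation-helix signature (H12, plus H4/H10 for
# full agonists).
_BINDING_SIGNATURE = {
    "BSR": (1.5, 0.15),
    "H3": (1.2, 0.15),
    "H7": (1.2, 0.15),
    "H2": (0.8, 0.12),
}
DEFAULT_EFFECT_SIZES: dict[str, dict[str, tuple[float, float]]] = {
    "agonist": {
        **_BINDING_SIGNATURE,
        "H12": (2.0, 0.15),
        "H4": (1.2, 0.15),
        "H10": (1.2, 0.15),
    },
    "partial_agonist": {**_BINDING_SIGNATURE, "H12": (0.7, 0.10)},
    "inverse_agonist": dict(_BINDING_SIGNATURE),
    "null": {},
}

DEFAULT_CLASS_PROPORTIONS = {
    "agonist": 13 / 38,
    "partial_agonist": 13 / 38,
    "inverse_agonist": 12 / 38,
}


def simulate_compound_library(
    n: int = 38,
    class_proportions: Mapping[str, float] | None = None,
    effect_sizes: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    occupancy: float = 1.0,
) -> list[CompoundSpec]:
    """Draw a compound library with planted region effects.

    Class counts follow ``class_proportions`` (largest-remainder rounding);
    per-compound effect sizes are drawn from the per-class distributions in
    ``effect_sizes`` (defaults above) and truncated at 0.
    """
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    for cls in props:
        if cls not in PHARM_CLASSES:
            raise ValueError(f"unknown pharmacological class {cls!r}")
    total = sum(props.values())
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ValueError("class proportions must sum to 1")
    sizes = effect_sizes or DEFAULT_EFFECT_SIZES

    classes = sorted(props)  # deterministic order
    quotas = {c: n * props[c] for c in classes}
    counts = {c: int(quotas[c]) for c in classes}
    for c in sorted(classes, key=lambda c: quotas[c] - counts[c], reverse=True)[
        : n - sum(counts.values())
    ]:
        counts[c] += 1

    rng = np.random.default_rng(seed)
    compounds: list[CompoundSpec] = []
    i = 0
    for cls in classes:
        for _ in range(counts[cls]):
            i += 1
            effects = {
                region: float(max(rng.normal(mu, sd), 0.0))
                for region, (mu, sd) in sizes.get(cls, {}).items()
            }
            compounds.append(
                CompoundSpec(
                    id=f"cpd{i:02d}",
                    pharm_class=cls,
                    region_effects=effects,
                    occupancy=occupancy,
                )
            )
    return compounds


def region_score(
    protein: ProteinModel,
    compound: CompoundSpec | None,
    region: str,
    timepoint: float,
) -> float:
    """Planted regional stabilisation score: noise-free regional d%D.

    Mean exchanged fraction over the region's non-proline residues, compound
    minus vehicle, times 100.  Protection gives negative scores.
    """
    res = protein.region_residues(region)
    idx = res - protein.first_index
    fr_c = _fraction_grid(protein, compound, [timepoint])[idx, 0]
    fr_v = _fraction_grid(protein, None, [timepoint])[idx, 0]
    return float(100.0 * (fr_c.mean() - fr_v.mean()))


@dataclass(frozen=True)
class LinkSpec:
    """Linear coupling of one assay readout to a planted regional score."""

    assay: str
    score_region: str
    score_timepoint: float
    intercept: float
    slope: float
    noise_sd: float
    scores: Mapping[str, float]  # compound id -> planted score

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        object.__setattr__(self, "scores", dict(self.scores))


@dataclass(frozen=True)
class AssayLinkModel:
    """Per-assay linear link models (AlphaScreen RLU, dTm degC, fold change)."""

    links: Mapping[str, LinkSpec]

    def __post_init__(self) -> None:
        object.__setattr__(self, "links", dict(self.links))


# (region, timepoint_s, slope per %D point, intercept, population R^2).
# Couplings emulate the empirical structure-activity pattern: coactivator
# recruitment tracks activation-helix (H12) stability at 10 s, thermal
# stability tracks the ligand-pocket beta-sheet region, and cell-reporter
# activity tracks H2 stability at the long timepoint.
DEFAULT_LINK_TARGETS: dict[str, tuple[str, float, float, float, float]] = {
    "alphascreen": ("H12", 10.0, -600.0, 2000.0, 0.64),
    "thermal_shift": ("BSR", 10.0, -0.30, 4.0, 0.54),
    "cell_reporter": ("H2", 14400.0, -0.15, 1.0, 0.51),
}


def default_assay_links(
    protein: ProteinModel,
    compounds: Sequence[CompoundSpec],
    targets: Mapping[str, tuple[str, float, float, float, float]] | None = None,
) -> AssayLinkModel:
    """Build link models whose noise is tuned to a population R^2.

    For a linear link ``y = a + b*s + e`` the population R^2 against the
    score ``s`` is ``b^2 Var(s) / (b^2 Var(s) + sd(e)^2)``, so the noise SD
    that realises a target R^2 is ``|b| * SD(s) * sqrt((1 - R^2)/R^2)``.
    SD(s) is taken over the actual library, making the population value
    exact for the library at hand.
    """
    targets = dict(targets or DEFAULT_LINK_TARGETS)
    links = {}
    for assay, (region, tp, slope, intercept, r2) in targets.items():
        scores = {
            c.id: region_score(protein, c, region, tp) for c in compounds
        }
        sd_s = float(np.std(list(scores.values()), ddof=0))
        if r2 <= 0 or r2 > 1:
            raise ValueError("population R^2 must lie in (0, 1]")
        noise_sd = abs(slope) * sd_s * math.sqrt((1.0 - r2) / r2)
        links[assay] = LinkSpec(
            assay=assay,
            score_region=region,
            score_timepoint=tp,
            intercept=intercept,
            slope=slope,
            noise_sd=noise_sd,
            scores=scores,
        )
    return AssayLinkModel(links=links)


def simulate_activities(
    compounds: Sequence[CompoundSpec],
    link_model: AssayLinkModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Functional-assay readouts, linear in the planted scores plus noise.

    Returns a tidy frame with columns ``compound``, ``assay``, ``value``.
    Deterministic given the seed; raises if a compound lacks a score.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for assay in sorted(link_model.links):
        spec = link_model.links[assay]
        for c in compounds:
            if c.id not in spec.scores:
                raise ValueError(
                    f"compound {c.id!r} has no planted {assay!r} score"
                )
            val = spec.intercept + spec.slope * spec.scores[c.id]
            val += rng.normal(0.0, spec.noise_sd)
            rows.append((c.id, assay, val))
    return pd.DataFrame(rows, columns=["compound", "assay", "value"])


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    protein: ProteinModel,
    peptides: Sequence[Peptide],
    compounds: Sequence[CompoundSpec],
    config: SimulationConfig,
    vehicle_id: str = "vehicle",
    paired_vehicle: bool = True,
    raw: bool = False,
) -> pd.DataFrame:
    """Tidy observation table for vehicle plus every compound.

    Columns: ``peptide_id``, ``condition``, ``experiment``, ``timepoint_s``,
    ``replicate`` and ``percent_d`` (or centroid columns when ``raw``).

    With ``paired_vehicle`` (the default) each compound constitutes one
    differential experiment with its own freshly measured vehicle arm, as
    when a screen is acquired as N separate compound-versus-control runs;
    the ``experiment`` column carries the compound id for both arms.  With
    ``paired_vehicle=False`` a single shared vehicle arm is simulated
    (``experiment`` equals the condition id).  Byte-identical output for
    identical inputs and seed.
    """
    rng = np.random.default_rng(config.seed)
    veh_clean = peptide_percent_d(protein, peptides, None, config.timepoints)
    frames = []
    runs: list[tuple[str, str, np.ndarray]] = []  # (condition, experiment, clean)
    if not paired_vehicle:
        runs.append((vehicle_id, vehicle_id, veh_clean))
    for c in compounds:
        clean = peptide_percent_d(protein, peptides, c, config.timepoints)
        if paired_vehicle:
            runs.append((vehicle_id, c.id, veh_clean))
        runs.append((c.id, c.id, clean))
    for cond_id, exp_id, clean in runs:
        noise = rng.normal(
            0.0,
            config.noise_sd_percent_d,
            size=(len(peptides), len(config.timepoints), config.n_replicates),
        )
        vals = np.clip(clean[:, :, None] + noise, 0.0, 100.0)
        idx = pd.MultiIndex.from_product(
            [
                [p.id for p in peptides],
                list(config.timepoints),
                range(1, config.n_replicates + 1),
            ],
            names=["peptide_id", "timepoint_s", "replicate"],
        )
        df = pd.DataFrame({"percent_d": vals.ravel()}, index=idx).reset_index()
        df.insert(1, "condition", cond_id)
        df.insert(2, "experiment", exp_id)
        if raw:
            pep_by_id = {p.id: p for p in peptides}
            parts = []
            for pid, sub in df.groupby("peptide_id", sort=False):
                undeut, obs, dmax = _percent_d_to_centroids(
                    sub["percent_d"].to_numpy(), pep_by_id[pid], config
                )
                parts.append(
                    sub.drop(columns="percent_d").assign(
                        undeut_mz=undeut, obs_mz=obs, dmax_mz=dmax
                    )
                )
            df = pd.concat(parts, ignore_index=True)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ScreenStudy:
    """A complete simulated screening study with its ground truth."""

    protein: ProteinModel
    peptides: tuple[Peptide, ...]
    compounds: tuple[CompoundSpec, ...]
    config: SimulationConfig
    observations: pd.DataFrame
    link_model: AssayLinkModel
    activities: pd.DataFrame
    vehicle_id: str = "vehicle"

    @property
    def classes(self) -> dict[str, str]:
        return {c.id: c.pharm_class for c in self.compounds}


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def simulate_screen_study(
    seed: int = 0,
    n_compounds: int = 38,
    n_replicates: int = 5,
    class_proportions: Mapping[str, float] | None = None,
    effect_sizes: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    noise_sd_percent_d: float = 1.5,
    timepoints: Sequence[float] = SCREEN_TIMEPOINTS,
    link_targets: Mapping[str, tuple[str, float, float, float, float]] | None = None,
    raw: bool = False,
) -> ScreenStudy:
    """One-call simulation of the default two-timepoint screening study.

    38 compounds in three pharmacological classes, 54-peptide map at ~98%
    coverage, 5 replicates, replicate noise 1.5 percentage points, and
    assay readouts coupled to planted regional scores.  All randomness
    derives from ``seed``.
    """
    s_prot, s_map, s_lib, s_obs, s_act = _child_seeds(seed, 5)
    protein = build_default_protein(seed=s_prot)
    peptides = generate_peptide_map(
        protein.sequence, first_index=protein.first_index, seed=s_map
    )
    compounds = simulate_compound_library(
        n=n_compounds,
        class_proportions=class_proportions,
        effect_sizes=effect_sizes,
        seed=s_lib,
    )
    config = SimulationConfig(
        timepoints=tuple(timepoints),
        n_replicates=n_replicates,
        noise_sd_percent_d=noise_sd_percent_d,
        seed=s_obs,
    )
    observations = simulate_dataset(protein, peptides, compounds, config, raw=raw)
    link_model = default_assay_links(protein, compounds, targets=link_targets)
    activities = simulate_activities(compounds, link_model, seed=s_act)
    return ScreenStudy(
        protein=protein,
        peptides=tuple(peptides),
        compounds=tuple(compounds),
        config=config,
        observations=observations,
        link_model=link_model,
        activities=activities,
    )


def perturbed_regions(compounds: Sequence[CompoundSpec]) -> set[str]:
    """Names of regions carrying a nonzero planted effect in any compound."""
    out: set[str] = set()
    for c in compounds:
        out |= {r for r, d in c.region_effects.items() if d > 0}
    return out


def peptides_overlapping_regions(
    protein: ProteinModel,
    peptides: Sequence[Peptide],
    regions: set[str],
) -> set[str]:
    """Peptide ids whose exchangeable residues intersect the given regions."""
    region_res: set[int] = set()
    for name in regions:
        region_res |= set(protein.region_residues(name).tolist())
    return {
        p.id
        for p in peptides
        if region_res & set(exchangeable_positions(p))
    }
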