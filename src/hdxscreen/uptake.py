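"""Peptide-level deuterium uptake.

Converts mass-spectral centroids into percent deuterium incorporation (%D)
and assembles per-condition uptake curves.  %D is defined per peptide
envelope relative to two reference samples: the undeuterated control (0%)
and a maximally deuterated ``Dmax`` control (100%).  Using the empirical
Dmax centroid as the 100% reference absorbs back-exchange losses, so no
separate back-exchange factor appears in the formula.

Exchangeable residues follow the standard HDX bookkeeping: the first two
residues of a peptide lose their deuterium during digestion/handling and
prolines carry no backbone amide hydrogen, so both are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Peptide",
    "CentroidTriple",
    "UptakeCurve",
    "centroid_mz",
    "percent_deuterium",
    "exchangeable_positions",
    "exchangeable_residue_count",
    "build_curve",
]

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Peptide:
    """An identified peptic peptide, the unit of HDX measurement.

    Coordinates are 1-based, inclusive, in construct numbering (the first
    residue of the construct may be e.g. 265).  A peptide observed in more
    than one charge state is treated as distinct peptide ions, one
    :class:`Peptide` per charge.
    """

    id: str
    sequence: str
    start: int
    end: int
    charge: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.id!r}: span {self.start}-{self.end} does not "
                f"match sequence length {len(self.sequence)}"
            )
        if self.charge < 1:
            raise ValueError(f"peptide {self.id!r}: charge must be >= 1")
        bad = set(self.sequence) - _STANDARD_AA
        if bad:
            raise ValueError(
                f"peptide {self.id!r}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class CentroidTriple:
    """Centroid m/z of the undeuterated, observed and Dmax envelopes."""

    undeuterated_mz: float
    observed_mz: float
    dmax_mz: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.dmax_mz <= self.undeuterated_mz:
            raise ValueError(
                "degenerate Dmax control: fully deuterated centroid "
                f"({self.dmax_mz}) must exceed the undeuterated centroid "
                f"({self.undeuterated_mz})"
            )


def centroid_mz(mz_values, intensities) -> float:
    """Intensity-weighted mean m/z of a peptide isotope envelope."""
    mz = np.asarray(mz_values, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if mz.shape != inten.shape or mz.ndim != 1 or mz.size == 0:
        raise ValueError("mz_values and intensities must be equal-length 1-D arrays")
    if np.any(inten < 0):
        raise ValueError("intensities must be non-negative")
    total = inten.sum()
    if total == 0:
        raise ValueError("all intensities are zero; centroid undefined")
    return float(np.dot(mz, inten) / total)


def percent_deuterium(triple: CentroidTriple, warn_epsilon: float = 0.05) -> float:
    """Percent deuterium incorporation from a centroid triple.

    %D = 100 * (observed - undeuterated) / (dmax - undeuterated).

    The Dmax centroid comes from an empirically back-exchanged, maximally
    deuterated control, so this linear interpolation is simultaneously the
    uptake calculation and the back-exchange correction.  Values outside
    ``[0, 100]`` by more than ``warn_epsilon`` (as a fraction of the
    undeuterated-to-Dmax spacing) raise a warning but are returned as-is so
    the caller can decide how to treat noisy observations.
    """
    spacing = triple.dmax_mz - triple.undeuterated_mz
    frac = (triple.observed_mz - triple.undeuterated_mz) / spacing
    if frac < -warn_epsilon or frac > 1.0 + warn_epsilon:
        warnings.warn(
            f"observed centroid {triple.observed_mz} lies far outside the "
            f"[undeuterated, Dmax] window "
            f"[{triple.undeuterated_mz}, {triple.dmax_mz}]",
            stacklevel=2,
        )
    return 100.0 * frac


def exchangeable_positions(peptide: Peptide) -> tuple[int, ...]:
    """Construct-numbered residues of ``peptide`` that report on exchange.

    The first two residues of each peptide and all prolines are excluded.
    """
    return tuple(
        peptide.start + i
        for i in range(2, len(peptide.sequence))
        if peptide.sequence[i] != "P"
    )


def exchangeable_residue_count(peptide: Peptide) -> int:
    """Number of exchange-reporting residues (0 for peptides shorter than 3)."""
    return len(exchangeable_positions(peptide))


@dataclass(frozen=True)
class UptakeCurve:
    """Per-timepoint replicate summary of %D for one peptide and condition.

    ``table`` has columns ``timepoint_s``, ``mean_percent_d``, ``sd`` and
    ``n``, sorted by timepoint; ``sd`` is the n-1 sample SD and is NaN
    where only a single replicate was measured.
    """

    peptide_id: str
    condition: str
    table: pd.DataFrame


def build_curve(
    observations: pd.DataFrame, peptide_id: str, condition: str
) -> UptakeCurve:
    """Summarize replicate observations into an uptake curve.

    ``observations`` is a tidy frame with columns ``peptide_id``,
    ``condition``, ``timepoint_s``, ``replicate`` and ``percent_d``.
    """
    sel = observations[
        (observations["peptide_id"] == peptide_id)
        & (observations["condition"] == condition)
    ]
    if sel.empty:
        raise ValueError(
            f"no observations for peptide {peptide_id!r} under {condition!r}"
        )
    grouped = sel.groupby("timepoint_s")["percent_d"]
    table = (
        pd.DataFrame(
            {
                "mean_percent_d": grouped.mean(),
                "sd": grouped.std(ddof=1),  # NaN when n == 1
                "n": grouped.count(),
            }
        )
        .reset_index()
        .sort_values("timepoint_s", ignore_index=True)
    )
    return UptakeCurve(peptide_id=peptide_id, condition=condition, table=table)
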