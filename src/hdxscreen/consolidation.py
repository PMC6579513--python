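"""Residue-level consolidation of overlapping peptide values.

Collapses peptide-level %D or d%D values onto individual residues by a
weighted residue-averaging scheme: every peptide whose exchangeable-residue
set contains a residue contributes its value with weight 1/n_exchangeable,
so shorter peptides (which localise the signal better) dominate.  The first
two residues of each peptide and prolines never receive contributions.

The weight function is pluggable; inverse exchangeable length is the default
because it is the simplest monotone choice with the required direction.
Sequence coverage, by convention, is computed over full peptide spans.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .uptake import Peptide, exchangeable_positions, exchangeable_residue_count

__all__ = [
    "inverse_length_weight",
    "consolidate_to_residues",
    "sequence_coverage",
    "bfactor_attribute_table",
]


def inverse_length_weight(n_exchangeable: int) -> float:
    """Default peptide weight: 1 / number of exchangeable residues."""
    return 1.0 / n_exchangeable


def consolidate_to_residues(
    values: Mapping[str, float],
    peptides: Sequence[Peptide],
    weight: Callable[[int], float] = inverse_length_weight,
    first_index: int | None = None,
    length: int | None = None,
) -> pd.DataFrame:
    """Weighted per-residue consolidation of peptide-level values.

    Parameters
    ----------
    values
        Peptide id -> value (%D or d%D).  Peptides in the map without a
        value are ignored; a valued peptide with zero exchangeable residues
        is an error.
    peptides
        The peptide map (geometry provider).
    weight
        Weight as a function of the exchangeable-residue count.
    first_index, length
        Optional explicit residue range of the output table (construct
        numbering).  Defaults to the range spanned by the peptide map.

    Returns
    -------
    DataFrame indexed by ``residue`` with columns ``value`` (NaN where
    missing), ``depth`` (number of contributing peptides) and ``missing``.
    Residues with depth 0 are missing, never zero.
    """
    by_id = {p.id: p for p in peptides}
    contributing = []
    for pid, val in values.items():
        if pid not in by_id:
            raise KeyError(f"value given for unknown peptide {pid!r}")
        if val is None or (isinstance(val, float) and np.isnan(val)):
            continue
        pep = by_id[pid]
        n_ex = exchangeable_residue_count(pep)
        if n_ex == 0:
            raise ValueError(
                f"peptide {pid!r} has no exchangeable residues but carries a value"
            )
        contributing.append((pep, float(val), weight(n_ex)))

    if first_index is None:
        first_index = min(p.start for p in peptides)
    if length is None:
        length = max(p.end for p in peptides) - first_index + 1
    residues = np.arange(first_index, first_index + length)

    wsum = np.zeros(length)
    vsum = np.zeros(length)
    depth = np.zeros(length, dtype=int)
    for pep, val, w in contributing:
        idx = np.asarray(exchangeable_positions(pep)) - first_index
        idx = idx[(idx >= 0) & (idx < length)]
        wsum[idx] += w
        vsum[idx] += w * val
        depth[idx] += 1

    with np.errstate(invalid="ignore"):
        value = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    return pd.DataFrame(
        {"value": value, "depth": depth, "missing": depth == 0},
        index=pd.Index(residues, name="residue"),
    )


def sequence_coverage(
    peptides: Sequence[Peptide],
    sequence_length: int,
    first_index: int = 1,
) -> float:
    """Percent of the sequence covered by the union of full peptide spans."""
    covered = np.zeros(sequence_length, dtype=bool)
    last = first_index + sequence_length - 1
    for pep in peptides:
        if pep.start < first_index or pep.end > last:
            raise ValueError(
                f"peptide {pep.id!r} ({pep.start}-{pep.end}) outside sequence "
                f"[{first_index}, {last}]"
            )
        covered[pep.start - first_index : pep.end - first_index + 1] = True
    return 100.0 * covered.sum() / sequence_length


def bfactor_attribute_table(residue_map: pd.DataFrame) -> pd.DataFrame:
    """Two-column residue/value list for B-factor substitution by external tools.

    Missing residues are dropped; writing into a coordinate file is left to
    structure-handling software.
    """
    out = residue_map.loc[~residue_map["missing"], ["value"]].reset_index()
    return out[["residue", "value"]]
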