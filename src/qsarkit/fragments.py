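"""Fragment class-frequency enrichment and class-exclusive fragment detection.

A "fragment" is a binary fingerprint bit (substructure key); presence is
per-molecule.  For a fragment and a class, the frequency statistic is the
enrichment ratio

    frequency = (N_fragment_class / N_class) / (N_fragment_total / N_total)

i.e. the fragment's prevalence within the class normalised by its prevalence
over all molecules.  A value of 1 means no enrichment; a fragment exclusive
to a class attains N_total / N_class there and 0 in the other class, and the
statistic satisfies Σ_class (N_class / N_total) · frequency = 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .descriptors import DescriptorMatrix


class FragmentError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentFrequencyRecord:
    fragment_id: str
    class_label: str
    N_fragment_class: int
    N_class: int
    N_fragment_total: int
    N_total: int
    frequency: float

    def __post_init__(self) -> None:
        if not (0 <= self.N_fragment_class <= min(self.N_class, self.N_fragment_total)):
            raise FragmentError(f"{self.fragment_id}: inconsistent class counts")
        if self.N_fragment_total > self.N_total:
            raise FragmentError(f"{self.fragment_id}: N_fragment_total > N_total")
        if (self.frequency == 0) != (self.N_fragment_class == 0):
            raise FragmentError(f"{self.fragment_id}: frequency/count mismatch")


def _binary_column(matrix: DescriptorMatrix, fragment_id: str) -> np.ndarray:
    if fragment_id not in matrix.data.columns:
        raise FragmentError(f"unknown fragment column {fragment_id!r}")
    if matrix.provenance.get(fragment_id) != "fingerprint_bit":
        raise FragmentError(f"{fragment_id!r} is not a fingerprint-bit column")
    return matrix.data[fragment_id].to_numpy(dtype=float).astype(bool)


def _class_masks(
    matrix: DescriptorMatrix, class_map: Mapping[str, str]
) -> dict[str, np.ndarray]:
    ids = matrix.compound_ids
    missing = [i for i in ids if i not in class_map]
    if missing:
        raise FragmentError(f"compounds without a class label: {missing}")
    labels = sorted({class_map[i] for i in ids})
    masks = {
        lab: np.array([class_map[i] == lab for i in ids], dtype=bool) for lab in labels
    }
    empty = [lab for lab, m in masks.items() if not m.any()]
    if empty:
        raise FragmentError(f"empty class(es): {empty}")
    return masks


def fragment_frequency(
    fragment_id: str,
    class_label: str,
    matrix: DescriptorMatrix,
    class_map: Mapping[str, str],
) -> FragmentFrequencyRecord:
    """Class-frequency enrichment of one fragment in one class."""
    present = _binary_column(matrix, fragment_id)
    masks = _class_masks(matrix, class_map)
    if class_label not in masks:
        raise FragmentError(f"unknown class {class_label!r}; have {sorted(masks)}")
    in_class = masks[class_label]
    n_total = int(present.size)
    n_class = int(in_class.sum())
    n_frag_total = int(present.sum())
    n_frag_class = int((present & in_class).sum())
    if n_frag_total == 0:
        freq = 0.0
    else:
        freq = (n_frag_class / n_class) / (n_frag_total / n_total)
    return FragmentFrequencyRecord(
        fragment_id=fragment_id,
        class_label=class_label,
        N_fragment_class=n_frag_class,
        N_class=n_class,
        N_fragment_total=n_frag_total,
        N_total=n_total,
        frequency=freq,
    )


def find_exclusive_fragments(
    matrix: DescriptorMatrix,
    class_map: Mapping[str, str],
    relaxed_present: float = 0.9,
    relaxed_absent: float = 0.1,
) -> dict[str, dict[str, list[str]]]:
    """Fragments confined to one class.

    For each class, the ``strict`` list holds fragments present in every
    molecule of that class and absent from every molecule of the other
    class(es); the ``relaxed`` list uses prevalence thresholds instead
    (>= ``relaxed_present`` within the class, <= ``relaxed_absent`` outside).
    """
    masks = _class_masks(matrix, class_map)
    if len(masks) < 2:
        raise FragmentError("need at least two classes")
    out: dict[str, dict[str, list[str]]] = {
        lab: {"strict": [], "relaxed": []} for lab in masks
    }
    for col in matrix.fingerprint_columns():
        present = _binary_column(matrix, col)
        prev = {lab: present[m].mean() for lab, m in masks.items()}
        for lab in masks:
            others = [p for l2, p in prev.items() if l2 != lab]
            if prev[lab] == 1.0 and all(p == 0.0 for p in others):
                out[lab]["strict"].append(col)
            if prev[lab] >= relaxed_present and all(p <= relaxed_absent for p in others):
                out[lab]["relaxed"].append(col)
    return out


def find_common_fragments(
    matrix: DescriptorMatrix,
    class_map: Mapping[str, str],
    min_prevalence: float = 0.9,
) -> list[str]:
    """Fragments with prevalence >= min_prevalence in every class."""
    if not (0 < min_prevalence <= 1):
        raise FragmentError(f"min_prevalence must be in (0,1], got {min_prevalence}")
    masks = _class_masks(matrix, class_map)
    common = []
    for col in matrix.fingerprint_columns():
        present = _binary_column(matrix, col)
        if all(present[m].mean() >= min_prevalence for m in masks.values()):
            common.append(col)
    return common


def frequency_table(
    matrix: DescriptorMatrix,
    class_map: Mapping[str, str],
    fragments: Sequence[str] | None = None,
) -> list[FragmentFrequencyRecord]:
    """Frequency records for every (fragment, class) pair."""
    masks = _class_masks(matrix, class_map)
    cols = list(fragments) if fragments is not None else matrix.fingerprint_columns()
    return [
        fragment_frequency(col, lab, matrix, class_map)
        for col in cols
        for lab in sorted(masks)
    ]


def write_frequency_table(records: Sequence[FragmentFrequencyRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "fragment_id",
                "class",
                "N_fragment_class",
                "N_class",
                "N_fragment_total",
                "N_total",
                "frequency",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.fragment_id,
                    r.class_label,
                    r.N_fragment_class,
                    r.N_class,
                    r.N_fragment_total,
                    r.N_total,
                    f"{r.frequency:.6g}",
                ]
            )
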