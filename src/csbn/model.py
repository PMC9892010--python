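"""Core domain types for cryo-slicing blue native (csBN-MS) complexome profiling.

A blue native gel lane is cut into thin slices (default 245 at 0.3 mm), each
slice is analysed by LC-MS/MS, and every protein ends up with an abundance
value per slice -- its abundance-mass profile.  These types carry the data
between the pipeline stages: slice-resolved peptide evidence in, profile
matrices with per-value reliability scores out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Number of gel slices in the reference experimental setup.
DEFAULT_N_SLICES = 245

#: Width of one cryo-slice in millimetres.
DEFAULT_SLICE_WIDTH_MM = 0.3


@dataclass(frozen=True)
class PeptideEvidence:
    """One quantified peptide signal (peak volume) in one slice run.

    Parameters
    ----------
    peptide_id
        Identifier of the peptide sequence (charge-state collapsed).
    protein_id
        Protein (group) the peptide is assigned to.
    run_index
        1-based gel slice / LC-MS run number.
    mz
        Mass-to-charge ratio in thomson; must be positive.
    elution_time
        Chromatographic elution time in minutes.
    intensity
        Peak volume in arbitrary ion counts; must be strictly positive.
    is_specific
        True when the peptide maps to exactly one protein group.
    """

    peptide_id: str
    protein_id: str
    run_index: int
    mz: float
    elution_time: float
    intensity: float
    is_specific: bool = True

    def __post_init__(self) -> None:
        if self.run_index < 1:
            raise ValueError(
                f"run_index must be >= 1 (slice numbers are 1-based), got {self.run_index}"
            )
        if not self.intensity > 0:
            raise ValueError(f"intensity must be > 0, got {self.intensity}")
        if not self.mz > 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")


@dataclass(frozen=True)
class RunMetadata:
    """Geometry of the sliced gel lane."""

    slice_width_mm: float = DEFAULT_SLICE_WIDTH_MM
    n_slices: int = DEFAULT_N_SLICES

    def __post_init__(self) -> None:
        if not self.slice_width_mm > 0:
            raise ValueError("slice_width_mm must be positive")
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")


class ProfileSet:
    """Protein x slice abundance matrix with per-value reliability scores.

    Abundances are non-negative molecular-abundance units (ridge-relative,
    see :mod:`csbn.quantify`); reliability values live in [0, 1] where 0
    marks a value that carries no information and 1 maximum confidence.
    Optional per-protein annotations (molecular mass in kDa, compartment,
    functional category) ride along as a DataFrame indexed by protein id.
    """

    def __init__(
        self,
        protein_ids: Sequence[str],
        abundance: np.ndarray,
        reliability: np.ndarray | None = None,
        annotations: pd.DataFrame | None = None,
    ) -> None:
        self.protein_ids = list(protein_ids)
        abundance = np.asarray(abundance, dtype=float)
        if abundance.ndim != 2 or abundance.shape[0] != len(self.protein_ids):
            raise ValueError(
                f"abundance must be (n_proteins, n_slices), got {abundance.shape} "
                f"for {len(self.protein_ids)} proteins"
            )
        if np.any(abundance < 0):
            i, j = np.argwhere(abundance < 0)[0]
            raise ValueError(
                f"abundance must be non-negative; negative value for protein "
                f"'{self.protein_ids[i]}' at slice {j + 1}"
            )
        self.abundance = abundance
        if reliability is None:
            reliability = np.ones_like(abundance)
        else:
            reliability = np.asarray(reliability, dtype=float)
            if reliability.shape != abundance.shape:
                raise ValueError("reliability must match abundance shape")
            if np.any((reliability < 0) | (reliability > 1)):
                raise ValueError("reliability values must lie in [0, 1]")
        self.reliability = reliability
        self.annotations = annotations
        self._index = {p: i for i, p in enumerate(self.protein_ids)}

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_slices(self) -> int:
        return self.abundance.shape[1]

    def profile(self, protein_id: str) -> np.ndarray:
        """Abundance vector of one protein (view, length ``n_slices``)."""
        return self.abundance[self._index[protein_id]]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __len__(self) -> int:
        return self.n_proteins

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileSet):
            return NotImplemented
        return (
            self.protein_ids == other.protein_ids
            and np.array_equal(self.abundance, other.abundance)
            and np.array_equal(self.reliability, other.reliability)
        )


def filter_identifications(evidence: Iterable[PeptideEvidence]) -> set[str]:
    """Apply the identification filter and return retained protein ids.

    A protein is retained iff it has at least two distinct protein-specific
    peptides, or exactly one specific peptide that was observed in at least
    three distinct slices.  Proteins identified by a single specific peptide
    seen in fewer than three slices are discarded as unreliable one-hit
    identifications.
    """
    peptides: dict[str, set[str]] = {}
    slices: dict[str, dict[str, set[int]]] = {}
    for ev in evidence:
        if not ev.is_specific:
            continue
        peptides.setdefault(ev.protein_id, set()).add(ev.peptide_id)
        slices.setdefault(ev.protein_id, {}).setdefault(ev.peptide_id, set()).add(
            ev.run_index
        )
    retained: set[str] = set()
    for prot, peps in peptides.items():
        if len(peps) >= 2:
            retained.add(prot)
        elif len(peps) == 1:
            (pep,) = peps
            if len(slices[prot][pep]) >= 3:
                retained.add(prot)
    return retained
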