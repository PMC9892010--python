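"""Ground-truth complexome simulator for end-to-end pipeline testing.

The generator states a simple world with the statistical structure the
pipeline assumes and real experiments show: complexes with log-uniform
native masses between 80 and 3,800 kDa and abundances spanning six orders
of magnitude; proteins that belong to several complexes (an average of 6.4
peaks per protein); Gaussian migration peaks on the gel; and peptide
evidence that is rank-1 per protein (abundance x ionization efficiency)
with lognormal measurement noise and detection-threshold dropout.  Truth
values are drawn directly from these distributions -- never computed with
pipeline code -- so recovery tests compare implementation against an
independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import MassCalibration
from .model import DEFAULT_N_SLICES, PeptideEvidence, ProfileSet

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class TruthComplex:
    complex_id: str
    member_protein_ids: tuple[str, ...]
    mass_kda: float
    abundance: float
    sigma_slices: float

    def __post_init__(self) -> None:
        if not self.abundance > 0:
            raise ValueError("abundance must be > 0")
        if len(set(self.member_protein_ids)) != len(self.member_protein_ids):
            raise ValueError("duplicate members in complex")


@dataclass(frozen=True)
class GeneratorParams:
    """The stated world: defaults reflect the reference experiment."""

    mass_range_kda: tuple[float, float] = (80.0, 3800.0)
    abundance_decades: float = 6.0
    sigma_range_slices: tuple[float, float] = (1.5, 6.0)
    n_slices: int = DEFAULT_N_SLICES
    mean_memberships: float = 6.4
    efficiency_log_sigma: float = 1.0  # lognormal spread of ionization efficiencies
    mz_range: tuple[float, float] = (400.0, 1200.0)
    elution_range_min: tuple[float, float] = (10.0, 120.0)
    profile_floor_rel: float = 1e-3    # additive floor relative to protein maximum


def generate_complexome(
    n_proteins: int,
    n_complexes: int,
    mean_memberships: float = 6.4,
    seed: int = 0,
    params: GeneratorParams | None = None,
) -> list[TruthComplex]:
    """Draw a ground-truth complexome.

    Complex masses are log-uniform over the gel's mass range, abundances
    log-uniform over ``abundance_decades`` decades, peak widths uniform
    over ``sigma_range_slices``.  Each protein joins ``Poisson(mean - 1) + 1``
    complexes chosen uniformly without replacement.  Deterministic under
    ``seed``.
    """
    if n_proteins < 1 or n_complexes < 1:
        raise ValueError("n_proteins and n_complexes must be >= 1")
    if mean_memberships < 1:
        raise ValueError("mean_memberships must be >= 1")
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(p.mass_range_kda[0]), np.log10(p.mass_range_kda[1])
    masses = 10.0 ** rng.uniform(lo, hi, n_complexes)
    abundances = 10.0 ** rng.uniform(0.0, p.abundance_decades, n_complexes)
    sigmas = rng.uniform(*p.sigma_range_slices, n_complexes)

    members: list[list[str]] = [[] for _ in range(n_complexes)]
    for i in range(n_proteins):
        pid = f"P{i + 1:04d}"
        k = min(int(rng.poisson(mean_memberships - 1.0)) + 1, n_complexes)
        for c in rng.choice(n_complexes, size=k, replace=False):
            members[c].append(pid)
    return [
        TruthComplex(
            f"C{c + 1:03d}", tuple(members[c]),
            float(masses[c]), float(abundances[c]), float(sigmas[c]),
        )
        for c in range(n_complexes)
    ]


def _extrapolated_slice(cal: MassCalibration, mass_kda: float) -> float:
    """Invert the calibration, falling back to a clamped extrapolation.

    Masses beyond the fitted asymptotes have no exact slice; they are
    placed just outside the corresponding gel end, matching the flagged
    "peak outside the gel" behaviour of real profiles.
    """
    try:
        return float(cal.mass_to_slice(mass_kda))
    except ValueError:
        lo, hi = cal.params[0], cal.params[1]
        y = math.log10(mass_kda)
        eps = 1e-4 * (hi - lo)
        y = min(max(y, lo + eps), hi - eps)
        s = float(cal.mass_to_slice(10.0**y))
        return min(max(s, -20.0), cal.n_slices + 20.0)


def render_profiles(
    truth: list[TruthComplex],
    cal: MassCalibration,
    noise_sigma: float = 0.0,
    seed: int = 0,
    params: GeneratorParams | None = None,
) -> ProfileSet:
    """Render truth complexes into protein abundance-mass profiles.

    Each protein's profile is the sum, over its complexes, of a Gaussian
    centred at the complex's calibrated slice position with area
    proportional to the complex abundance, multiplied by per-value
    lognormal noise (sigma in natural-log space) and lifted by a small
    additive floor.  Profiles exist only on slices 1..n (gel-clipped).
    """
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    protein_ids = sorted({pid for c in truth for pid in c.member_protein_ids})
    idx = {pid: i for i, pid in enumerate(protein_ids)}
    x = np.arange(1, p.n_slices + 1, dtype=float)
    clean = np.zeros((len(protein_ids), p.n_slices))
    for c in truth:
        centre = _extrapolated_slice(cal, c.mass_kda)
        amp = c.abundance / (c.sigma_slices * SQRT_2PI)
        shape = amp * np.exp(-0.5 * ((x - centre) / c.sigma_slices) ** 2)
        for pid in c.member_protein_ids:
            clean[idx[pid]] += shape
    noisy = clean.copy()
    if noise_sigma > 0:
        noisy *= np.exp(rng.normal(0.0, noise_sigma, clean.shape))
    if p.profile_floor_rel > 0:
        peak = np.max(clean, axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        noisy += p.profile_floor_rel * peak
    return ProfileSet(protein_ids, noisy)


def render_peptide_observations(
    profiles: ProfileSet,
    peptides_per_protein: int = 6,
    dropout_threshold: float = 0.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    dropout_quantile: float | None = None,
    run_drift: dict[int, tuple[float, float]] | None = None,
    random_missing_rate: float = 0.0,
    params: GeneratorParams | None = None,
) -> list[PeptideEvidence]:
    """Render profiles into slice-resolved rank-1 peptide evidence.

    Per protein, a fixed lognormal ionization-efficiency vector is drawn;
    the intensity of peptide ``i`` in slice ``s`` is
    ``abundance[s] * efficiency[i] * lognormal noise``.  Cells below
    ``dropout_threshold`` (or below the given quantile of all intensities)
    are removed -- a detection-limit, not a random, missingness mechanism;
    ``random_missing_rate`` adds the random variant for robustness tests.
    Elution times are per peptide, with optional per-run linear drift
    ``t_obs = offset + slope * t`` (the known truth for alignment tests).
    """
    if peptides_per_protein < 1:
        raise ValueError("peptides_per_protein must be >= 1")
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    run_drift = run_drift or {}
    records: list[PeptideEvidence] = []
    all_cells: list[tuple[str, str, int, float, float, float]] = []
    for pi, pid in enumerate(profiles.protein_ids):
        eff = np.exp(rng.normal(0.0, p.efficiency_log_sigma, peptides_per_protein))
        mzs = rng.uniform(*p.mz_range, peptides_per_protein)
        times = rng.uniform(*p.elution_range_min, peptides_per_protein)
        prof = profiles.abundance[pi]
        noise = (
            np.exp(rng.normal(0.0, noise_sigma, (peptides_per_protein, prof.size)))
            if noise_sigma > 0
            else np.ones((peptides_per_protein, prof.size))
        )
        intensity = eff[:, None] * prof[None, :] * noise
        for i in range(peptides_per_protein):
            pep_id = f"{pid}_pep{i + 1:02d}"
            for s in range(prof.size):
                val = float(intensity[i, s])
                if val <= 0:
                    continue
                all_cells.append((pep_id, pid, s + 1, float(mzs[i]), float(times[i]), val))

    values = np.array([c[5] for c in all_cells])
    threshold = dropout_threshold
    if dropout_quantile is not None and values.size:
        threshold = max(threshold, float(np.quantile(values, dropout_quantile)))
    keep = values >= threshold if threshold > 0 else np.ones(values.size, dtype=bool)
    if random_missing_rate > 0:
        keep &= rng.random(values.size) >= random_missing_rate

    for (pep_id, pid, run, mz, t, val), k in zip(all_cells, keep):
        if not k:
            continue
        offset, slope = run_drift.get(run, (0.0, 1.0))
        records.append(
            PeptideEvidence(
                peptide_id=pep_id, protein_id=pid, run_index=run,
                mz=mz, elution_time=offset + slope * t, intensity=val,
                is_specific=True,
            )
        )
    return records


@dataclass
class SyntheticDataset:
    truth: list[TruthComplex]
    profiles: ProfileSet
    evidence: list[PeptideEvidence]
    seed: int
    params: GeneratorParams


def generate_dataset(
    n_proteins: int = 200,
    n_complexes: int = 60,
    mean_memberships: float = 6.4,
    noise_sigma: float = 0.0,
    peptides_per_protein: int = 6,
    seed: int = 0,
    cal: MassCalibration | None = None,
    params: GeneratorParams | None = None,
    evidence_noise_sigma: float | None = None,
    dropout_quantile: float | None = None,
) -> SyntheticDataset:
    """Convenience wrapper: complexome -> profiles -> evidence, one seed."""
    from .calibrate import fit_calibration

    p = params or GeneratorParams()
    cal = cal or fit_calibration(n_slices=p.n_slices)
    truth = generate_complexome(n_proteins, n_complexes, mean_memberships, seed, p)
    profiles = render_profiles(truth, cal, noise_sigma, seed + 1, p)
    evidence = render_peptide_observations(
        profiles,
        peptides_per_protein,
        seed=seed + 2,
        noise_sigma=evidence_noise_sigma if evidence_noise_sigma is not None else noise_sigma,
        dropout_quantile=dropout_quantile,
        params=p,
    )
    return SyntheticDataset(truth, profiles, evidence, seed, p)


def write_truth_table(truth: list[TruthComplex], path: str | Path) -> None:
    pd.DataFrame(
        {
            "complex_id": [c.complex_id for c in truth],
            "members": [";".join(c.member_protein_ids) for c in truth],
            "mass_kda": [c.mass_kda for c in truth],
            "abundance": [c.abundance for c in truth],
            "sigma_slices": [c.sigma_slices for c in truth],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
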