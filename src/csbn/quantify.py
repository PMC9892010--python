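"""Label-free protein quantification from slice-resolved peptide evidence.

The pipeline turns peptide peak volumes, measured per gel slice (one LC-MS
run per slice), into protein abundance-mass profiles:

1. elution times are aligned across runs (LOESS against the per-peptide
   median reference);
2. unidentified intensity features can be matched to identified peptides
   within ppm / minute tolerances (match-between-runs);
3. run-to-run intensity offsets are normalized to the local median over a
   40-slice window;
4. each protein's peptide x run intensity matrix is checked for internal
   consistency: every observed cell gets an expected peptide intensity
   value (EPV) predicted from the other cells, and a consistency weight
   that decays with the log-deviation from it;
5. qualified runs are merged by EPV-weighted least squares into a protein
   reference ridge (relative peptide ionization efficiencies);
6. the abundance at each slice is the EPV-weighted least-squares scale
   factor fitting the intensities of five consecutive slices to the ridge,
   with intensities below a local detectability threshold treated as
   missing, and a reliability score in [0, 1] summarising how many peptides
   supported the value and how consistent they were.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import DEFAULT_N_SLICES, PeptideEvidence, ProfileSet, filter_identifications

logger = logging.getLogger(__name__)

LOG2 = math.log(2.0)


# ---------------------------------------------------------------------------
# containers


@dataclass
class PeptideMatrix:
    """Peptide x run intensity matrix of one protein (NaN = missing)."""

    protein_id: str
    peptide_ids: list[str]
    runs: list[int]
    intensity: np.ndarray
    epv: np.ndarray | None = None
    weight: np.ndarray | None = None
    detect_threshold: np.ndarray | None = None
    epv_undefined: bool = False

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass(frozen=True)
class ReferenceRidge:
    """Relative ionization efficiencies of a protein's peptides (max = 1)."""

    protein_id: str
    peptide_ids: tuple[str, ...]
    ridge: np.ndarray

    def __post_init__(self) -> None:
        if np.any(~(self.ridge > 0)):
            raise ValueError("all ridge values must be > 0")


@dataclass(frozen=True)
class AbundanceEstimate:
    protein_id: str
    slice: int
    abundance: float
    reliability: float
    n_peptides_used: int
    mean_relative_deviation: float


@dataclass(frozen=True)
class QuantifyConfig:
    tol_ppm: float = 2.0
    tol_min: float = 1.0
    norm_half_window: int = 20          # 40-slice normalization span
    norm_min_peptides: int = 5
    epv_col_window: int = 10            # runs used for column-route predictions
    epv_min_predictions: int = 3
    epv_interp_half_window: int = 2     # 5-slice interpolation window
    detect_half_window_min: float = 1.5  # 3-minute co-elution window
    detect_percentile: float = 3.0
    detect_min_peptides: int = 10
    qualified_min_median_weight: float = 0.5
    abundance_half_window: int = 2      # 5 consecutive slices
    reliability_n0: float = 3.0
    reliability_d0: float = 1.0
    align_min_shared: int = 20
    align_lowess_frac: float = 0.5


# ---------------------------------------------------------------------------
# 1. elution-time alignment


def align_elution_times(
    evidence: Sequence[PeptideEvidence],
    min_shared: int = 20,
    lowess_frac: float = 0.5,
) -> list[PeptideEvidence]:
    """Correct systematic per-run elution-time shifts by LOESS regression.

    The reference is the median elution time of each peptide over all runs.
    For every run sharing at least ``min_shared`` peptides with the
    reference, the run-specific deviation is smoothed as a function of
    elution time (LOESS) and subtracted.  Runs with too few shared peptides
    are left uncorrected with a warning.
    """
    by_peptide: dict[str, list[float]] = {}
    for ev in evidence:
        by_peptide.setdefault(ev.peptide_id, []).append(ev.elution_time)
    reference = {p: float(np.median(t)) for p, t in by_peptide.items() if len(t) >= 2}

    runs = sorted({ev.run_index for ev in evidence})
    corrections: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for run in runs:
        run_ev = [ev for ev in evidence if ev.run_index == run and ev.peptide_id in reference]
        if len(run_ev) < min_shared:
            logger.warning(
                "run %d: only %d peptides shared with reference (< %d), left uncorrected",
                run, len(run_ev), min_shared,
            )
            continue
        t = np.array([ev.elution_time for ev in run_ev])
        delta = t - np.array([reference[ev.peptide_id] for ev in run_ev])
        smoothed = lowess(delta, t, frac=lowess_frac, it=2, return_sorted=True)
        corrections[run] = (smoothed[:, 0], smoothed[:, 1])

    out: list[PeptideEvidence] = []
    for ev in evidence:
        if ev.run_index in corrections:
            xt, yd = corrections[ev.run_index]
            corr = float(np.interp(ev.elution_time, xt, yd))
            out.append(replace(ev, elution_time=ev.elution_time - corr))
        else:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# 2. feature-to-identity matching


def match_features(
    feature_mz: np.ndarray,
    feature_time: np.ndarray,
    identity_mz: np.ndarray,
    identity_time: np.ndarray,
    tol_ppm: float = 2.0,
    tol_min: float = 1.0,
) -> np.ndarray:
    """Assign unidentified intensity features to identified peptides.

    A feature matches an identity when |dm/z| <= ``tol_ppm`` (relative to
    the identity m/z) and |dt| <= ``tol_min``.  Among multiple candidates
    the smallest ppm deviation wins; ties break on smallest |dt|.  Returns
    an int array of identity indices, -1 for unmatched features.
    """
    feature_mz = np.asarray(feature_mz, dtype=float)
    feature_time = np.asarray(feature_time, dtype=float)
    identity_mz = np.asarray(identity_mz, dtype=float)
    identity_time = np.asarray(identity_time, dtype=float)
    order = np.argsort(identity_mz)
    smz, stime = identity_mz[order], identity_time[order]

    result = np.full(feature_mz.shape, -1, dtype=int)
    for i, (fmz, ft) in enumerate(zip(feature_mz, feature_time)):
        half = fmz * tol_ppm * 1e-6 * 1.000001  # guard against edge rounding
        lo = np.searchsorted(smz, fmz - half, side="left")
        hi = np.searchsorted(smz, fmz + half, side="right")
        best = -1
        best_key = (np.inf, np.inf)
        for k in range(lo, hi):
            ppm = abs(fmz - smz[k]) / smz[k] * 1e6
            dt = abs(ft - stime[k])
            if ppm <= tol_ppm and dt <= tol_min and (ppm, dt) < best_key:
                best_key = (ppm, dt)
                best = int(order[k])
        result[i] = best
    return result


# ---------------------------------------------------------------------------
# 3. run normalization


def normalize_runs(
    intensity: pd.DataFrame,
    half_window: int = 20,
    min_peptides: int = 5,
) -> pd.Series:
    """Per-run scale factors from local-median normalization.

    ``intensity`` is peptide x run (columns = 1-based slice numbers, NaN =
    missing).  For each run, every peptide's intensity is compared with its
    median over the runs inside a window of ``2 * half_window`` slices
    around it; the run factor is the median of these ratios.  Runs with
    fewer than ``min_peptides`` usable peptides keep factor 1.0.

    Dividing a run's intensities by its factor removes global run-to-run
    offsets (injection amount, spray efficiency) without flattening the
    genuine abundance structure along the gel.
    """
    cols = list(intensity.columns)
    values = intensity.to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(cols)}
    factors = pd.Series(1.0, index=intensity.columns, dtype=float)
    for c in cols:
        j = col_pos[c]
        in_window = [col_pos[c2] for c2 in cols if abs(int(c2) - int(c)) <= half_window]
        window = values[:, in_window]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            consensus = np.nanmedian(window, axis=1)
        ratio = values[:, j] / consensus
        ok = np.isfinite(ratio) & (np.sum(np.isfinite(window), axis=1) >= 3)
        if ok.sum() < min_peptides:
            logger.warning(
                "run %s: %d usable peptides in +/-%d-slice window (< %d), factor 1.0",
                c, int(ok.sum()), half_window, min_peptides,
            )
            continue
        factors[c] = float(np.median(ratio[ok]))
    return factors


# ---------------------------------------------------------------------------
# 4. expected peptide intensity values (EPV)


def _kde_mode(values: np.ndarray) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth), evaluated at the samples."""
    return float(_kde_mode_rows(values[None, :])[0])


def _kde_mode_rows(preds: np.ndarray) -> np.ndarray:
    """Row-wise KDE modes of a (rows, n_predictions) array with NaN padding."""
    rows, _ = preds.shape
    finite = np.isfinite(preds)
    counts = finite.sum(axis=1)
    out = np.full(rows, np.nan)
    if not counts.any():
        return out

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.sqrt(np.nanvar(preds, axis=1, ddof=1))
        q75, q25 = np.nanpercentile(preds, [75, 25], axis=1)
    iqr = q75 - q25
    spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        bw = np.maximum(0.9 * spread * np.maximum(counts, 2) ** (-0.2), 1e-9)

    filled = np.where(finite, preds, 0.0)
    diff = (filled[:, :, None] - filled[:, None, :]) / bw[:, None, None]
    kernel = np.exp(-0.5 * diff**2)
    kernel *= finite[:, None, :]  # NaN samples contribute nothing
    density = kernel.sum(axis=2)
    density[~finite] = -np.inf
    argmax = np.argmax(density, axis=1)
    ok = counts > 0
    out[ok] = preds[ok, argmax[ok]]
    # degenerate rows: single sample or zero spread -> that value
    single = counts == 1
    if single.any():
        first = np.argmax(finite, axis=1)
        out[single] = preds[single, first[single]]
    return out


def compute_epv(matrix: PeptideMatrix, config: QuantifyConfig | None = None) -> PeptideMatrix:
    """Fill the matrix with expected peptide values and consistency weights.

    Every observed cell (i, j) receives predictions from the rest of the
    matrix under the rank-1 model log I[i, j] = log e_i + log a_j (peptide
    ionization efficiency x slice abundance): from every other peptide row k
    via the median pairwise row log-ratio, and from nearby runs l via the
    median pairwise column log-offset.  The EPV is the mode of a Gaussian
    kernel density over the log-intensity predictions; cells with too few
    predictions are interpolated from EPV-validated neighbours within a
    5-slice window.  The consistency weight is ``exp(-|log2 I - log2 EPV|)``.
    """
    cfg = config or QuantifyConfig()
    I = matrix.intensity
    p, r = I.shape
    if p < 2 or np.sum(np.any(np.isfinite(I), axis=0)) < 2:
        matrix.epv = np.full_like(I, np.nan)
        matrix.weight = np.where(np.isfinite(I), 1.0, np.nan)
        matrix.epv_undefined = True
        return matrix

    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.log2(I)
    observed = np.isfinite(L)

    # median pairwise row log-ratios rho[i, k] = log2(e_i / e_k)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.nanmedian(L[:, None, :] - L[None, :, :], axis=2)

    epv_log = np.full_like(L, np.nan)
    n_pred = np.zeros_like(L, dtype=int)
    for j in range(r):
        col_obs = observed[:, j]
        if not col_obs.any():
            continue
        lo, hi = max(0, j - cfg.epv_col_window), min(r, j + cfg.epv_col_window + 1)
        neighbours = [l for l in range(lo, hi) if l != j]
        # column offsets c[l] = median_i (L[i, j] - L[i, l])
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_offsets = np.nanmedian(L[:, [j]] - L[:, neighbours], axis=0)
        # predictions: rows (p-1 per cell) then columns
        preds_row = L[:, j][None, :] + rho          # (i, k): L[k, j] + rho[i, k]
        np.fill_diagonal(preds_row, np.nan)
        preds_col = L[:, neighbours] + col_offsets[None, :]
        preds = np.concatenate([preds_row, preds_col], axis=1)
        preds[~col_obs, :] = np.nan
        n_pred[:, j] = np.isfinite(preds).sum(axis=1)
        enough = col_obs & (n_pred[:, j] >= cfg.epv_min_predictions)
        if enough.any():
            modes = _kde_mode_rows(preds[enough])
            epv_log[enough, j] = modes

    # fallback: interpolate missing EPVs from validated neighbours (5-slice window)
    for i in range(p):
        valid = np.where(np.isfinite(epv_log[i]))[0]
        needs = np.where(observed[i] & ~np.isfinite(epv_log[i]))[0]
        for j in needs:
            near = valid[np.abs(valid - j) <= cfg.epv_interp_half_window]
            if near.size:
                epv_log[i, j] = float(np.interp(j, near, epv_log[i, near]))

    weight = np.full_like(L, np.nan)
    has_epv = observed & np.isfinite(epv_log)
    weight[has_epv] = np.exp(-np.abs(L[has_epv] - epv_log[has_epv]))
    weight[observed & ~np.isfinite(epv_log)] = 1.0  # no consistency information

    matrix.epv = np.where(np.isfinite(epv_log), 2.0**epv_log, np.nan)
    matrix.weight = weight
    matrix.epv_undefined = False
    return matrix


# ---------------------------------------------------------------------------
# 5. detectability threshold


def detectability_threshold(
    elution_times: np.ndarray,
    intensities: np.ndarray,
    target_time: float,
    half_window_min: float = 1.5,
    percentile: float = 3.0,
    min_peptides: int = 10,
) -> tuple[float, bool]:
    """Intensity floor below which a peptide would escape detection.

    The threshold is the given percentile (linear interpolation between
    order statistics) of the intensities of all peptides of the run that
    co-elute within ``2 * half_window_min`` minutes of ``target_time``.
    Returns ``(threshold, defined)``; with fewer than ``min_peptides``
    co-eluting peptides the threshold is undefined (NaN, False) and
    missingness downstream is treated as uninformative, never as zero
    abundance.
    """
    elution_times = np.asarray(elution_times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    mask = np.abs(elution_times - target_time) <= half_window_min
    if mask.sum() < min_peptides:
        return float("nan"), False
    return float(np.percentile(intensities[mask], percentile, method="linear")), True


# ---------------------------------------------------------------------------
# 6. reference ridge


def qualified_runs(matrix: PeptideMatrix, min_median_weight: float = 0.5) -> np.ndarray:
    """Column indices whose observed cells are internally consistent."""
    assert matrix.weight is not None, "compute_epv must run first"
    cols = []
    for j in range(matrix.n_runs):
        w = matrix.weight[:, j]
        w = w[np.isfinite(w)]
        if w.size and float(np.median(w)) >= min_median_weight:
            cols.append(j)
    return np.array(cols, dtype=int)


def build_reference_ridge(
    matrix: PeptideMatrix, config: QuantifyConfig | None = None
) -> ReferenceRidge:
    """Merge qualified runs into the protein's reference ridge.

    The anchor is the qualified run with the most assigned peptide
    intensities.  Every other qualified run is scaled onto the anchor by a
    weighted least-squares fit over shared peptides (weights = products of
    the EPV consistency weights), then the ridge is the weighted mean of the
    scaled intensities per peptide, normalized to a maximum of 1.
    """
    cfg = config or QuantifyConfig()
    if matrix.weight is None:
        compute_epv(matrix, cfg)
    I, W = matrix.intensity, matrix.weight
    assert W is not None
    qual = qualified_runs(matrix, cfg.qualified_min_median_weight)
    if qual.size == 0:
        raise ValueError(f"{matrix.protein_id}: no consistent evidence")

    counts = np.sum(np.isfinite(I[:, qual]), axis=0)
    anchor = int(qual[np.argmax(counts)])
    anchor_obs = np.isfinite(I[:, anchor])

    scaled_sum = np.zeros(matrix.n_peptides)
    weight_sum = np.zeros(matrix.n_peptides)
    for j in qual:
        if j == anchor:
            scale = 1.0
        else:
            shared = np.isfinite(I[:, j]) & anchor_obs
            if not shared.any():
                continue
            w = W[shared, j] * W[shared, anchor]
            x, y = I[shared, j], I[shared, anchor]
            denom = float(np.sum(w * x * x))
            if denom <= 0:
                continue
            scale = float(np.sum(w * x * y)) / denom
            if scale <= 0:
                continue
        obs = np.isfinite(I[:, j])
        scaled_sum[obs] += W[obs, j] * I[obs, j] * scale
        weight_sum[obs] += W[obs, j]

    covered = weight_sum > 0
    if not covered.any():
        raise ValueError(f"{matrix.protein_id}: no consistent evidence")
    ridge = np.full(matrix.n_peptides, np.nan)
    ridge[covered] = scaled_sum[covered] / weight_sum[covered]
    ridge = ridge / np.nanmax(ridge)
    return ReferenceRidge(
        matrix.protein_id,
        tuple(pid for pid, c in zip(matrix.peptide_ids, covered) if c),
        ridge[covered],
    )


# ---------------------------------------------------------------------------
# 7. abundance estimation + reliability


def reliability_score(
    n_peptides_used: int,
    mean_relative_deviation: float,
    n0: float = 3.0,
    d0: float = 1.0,
) -> float:
    """Reliability in [0, 1]: saturating in peptide count, decaying in deviation.

    ``score = (1 - exp(-n / n0)) * exp(-d / d0)`` with the deviation ``d``
    in log2 units.  Zero peptides give 0; many peptides with zero deviation
    approach 1.
    """
    if n_peptides_used <= 0:
        return 0.0
    score = (1.0 - math.exp(-n_peptides_used / n0)) * math.exp(
        -max(mean_relative_deviation, 0.0) / d0
    )
    return min(max(score, 0.0), 1.0)


def estimate_abundance(
    matrix: PeptideMatrix,
    ridge: ReferenceRidge,
    slice_index: int,
    config: QuantifyConfig | None = None,
) -> AbundanceEstimate:
    """EPV-weighted least-squares abundance of one protein at one slice.

    The measured peptide intensities of five consecutive slices (the slice
    +/- 2, truncated at the gel ends -- an oversampled gel makes this a
    sliding average, not a loss of resolution) are fitted to the reference
    ridge; the scale factor is the molecular abundance.  Intensities below
    the cell's detectability threshold count as missing.
    """
    cfg = config or QuantifyConfig()
    if matrix.weight is None:
        compute_epv(matrix, cfg)
    ridge_map = {pid: v for pid, v in zip(ridge.peptide_ids, ridge.ridge)}
    run_pos = {run: j for j, run in enumerate(matrix.runs)}
    window = [
        run_pos[s]
        for s in range(slice_index - cfg.abundance_half_window, slice_index + cfg.abundance_half_window + 1)
        if s in run_pos
    ]
    x, y, w, devs, pep_used = [], [], [], [], set()
    for i, pid in enumerate(matrix.peptide_ids):
        if pid not in ridge_map:
            continue
        for j in window:
            val = matrix.intensity[i, j]
            if not np.isfinite(val):
                continue
            if matrix.detect_threshold is not None:
                thr = matrix.detect_threshold[i, j]
                if np.isfinite(thr) and val < thr:
                    continue
            x.append(ridge_map[pid])
            y.append(val)
            w.append(matrix.weight[i, j] if np.isfinite(matrix.weight[i, j]) else 1.0)
            if matrix.epv is not None and np.isfinite(matrix.epv[i, j]):
                devs.append(abs(math.log2(val / matrix.epv[i, j])))
            pep_used.add(pid)
    if not x:
        return AbundanceEstimate(matrix.protein_id, slice_index, 0.0, 0.0, 0, 0.0)
    x_arr, y_arr, w_arr = np.array(x), np.array(y), np.array(w)
    denom = float(np.sum(w_arr * x_arr * x_arr))
    a = max(float(np.sum(w_arr * x_arr * y_arr)) / denom, 0.0) if denom > 0 else 0.0
    if a <= 0:
        return AbundanceEstimate(matrix.protein_id, slice_index, 0.0, 0.0, 0, 0.0)
    # deviation from the expected peptide values; without EPVs, from the fit
    if devs:
        dev = float(np.mean(devs))
    else:
        dev = float(np.mean(np.abs(np.log2(y_arr / (a * x_arr)))))
    rel = reliability_score(len(pep_used), dev, cfg.reliability_n0, cfg.reliability_d0)
    return AbundanceEstimate(matrix.protein_id, slice_index, a, rel, len(pep_used), dev)


# ---------------------------------------------------------------------------
# top level


def build_peptide_matrix(
    evidence: Iterable[PeptideEvidence],
    protein_id: str,
    n_slices: int = DEFAULT_N_SLICES,
) -> PeptideMatrix:
    """Collect one protein's specific evidence into a peptide x run matrix.

    Duplicate observations of the same peptide in the same run are summed
    (split peaks / repeated features).
    """
    cells: dict[tuple[str, int], float] = {}
    for ev in evidence:
        if ev.protein_id != protein_id or not ev.is_specific:
            continue
        key = (ev.peptide_id, ev.run_index)
        cells[key] = cells.get(key, 0.0) + ev.intensity
    peptide_ids = sorted({k[0] for k in cells})
    runs = list(range(1, n_slices + 1))
    intensity = np.full((len(peptide_ids), n_slices), np.nan)
    pep_pos = {p: i for i, p in enumerate(peptide_ids)}
    for (pid, run), val in cells.items():
        if 1 <= run <= n_slices:
            intensity[pep_pos[pid], run - 1] = val
    return PeptideMatrix(protein_id, peptide_ids, runs, intensity)


def attach_detectability_thresholds(
    matrix: PeptideMatrix,
    evidence: Sequence[PeptideEvidence],
    config: QuantifyConfig | None = None,
) -> PeptideMatrix:
    """Per-cell intensity floors from each run's co-eluting peptide population."""
    cfg = config or QuantifyConfig()
    by_run: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for run in {ev.run_index for ev in evidence}:
        sub = [ev for ev in evidence if ev.run_index == run]
        by_run[run] = (
            np.array([ev.elution_time for ev in sub]),
            np.array([ev.intensity for ev in sub]),
        )
    pep_time: dict[str, float] = {}
    for ev in evidence:
        if ev.protein_id == matrix.protein_id:
            pep_time.setdefault(ev.peptide_id, ev.elution_time)
    thr = np.full_like(matrix.intensity, np.nan)
    for i, pid in enumerate(matrix.peptide_ids):
        if pid not in pep_time:
            continue
        for j, run in enumerate(matrix.runs):
            if not np.isfinite(matrix.intensity[i, j]) or run not in by_run:
                continue
            times, intens = by_run[run]
            value, defined = detectability_threshold(
                times, intens, pep_time[pid],
                cfg.detect_half_window_min, cfg.detect_percentile, cfg.detect_min_peptides,
            )
            if defined:
                thr[i, j] = value
    matrix.detect_threshold = thr
    return matrix


def quantify_evidence(
    evidence: Sequence[PeptideEvidence],
    n_slices: int = DEFAULT_N_SLICES,
    config: QuantifyConfig | None = None,
    align: bool = False,
    normalize: bool = False,
    apply_thresholds: bool = False,
) -> tuple[ProfileSet, pd.DataFrame]:
    """Run the full quantification chain and return profiles plus details.

    Returns a :class:`ProfileSet` (abundance + reliability matrices over
    the retained proteins) and a tidy per-value details table
    (protein_id, slice, n_peptides, deviation, reliability) mirroring the
    per-datapoint quantification details a profile viewer would expose.
    """
    cfg = config or QuantifyConfig()
    if align:
        evidence = align_elution_times(evidence, cfg.align_min_shared, cfg.align_lowess_frac)
    if normalize:
        df = pd.DataFrame(
            [(ev.peptide_id, ev.run_index, ev.intensity) for ev in evidence],
            columns=["peptide_id", "run_index", "intensity"],
        ).pivot_table(index="peptide_id", columns="run_index", values="intensity", aggfunc="sum")
        factors = normalize_runs(df, cfg.norm_half_window, cfg.norm_min_peptides)
        evidence = [
            replace(ev, intensity=ev.intensity / float(factors.get(ev.run_index, 1.0)))
            for ev in evidence
        ]

    retained = sorted(filter_identifications(evidence))
    profiles = np.zeros((len(retained), n_slices))
    reliab = np.zeros((len(retained), n_slices))
    rows = []
    for idx, prot in enumerate(retained):
        matrix = build_peptide_matrix(evidence, prot, n_slices)
        compute_epv(matrix, cfg)
        if apply_thresholds:
            attach_detectability_thresholds(matrix, evidence, cfg)
        try:
            ridge = build_reference_ridge(matrix, cfg)
        except ValueError:
            logger.warning("%s: no consistent evidence, profile left empty", prot)
            continue
        for s in range(1, n_slices + 1):
            est = estimate_abundance(matrix, ridge, s, cfg)
            profiles[idx, s - 1] = est.abundance
            reliab[idx, s - 1] = est.reliability
            if est.n_peptides_used:
                rows.append(
                    (prot, s, est.n_peptides_used, est.mean_relative_deviation, est.reliability)
                )
    details = pd.DataFrame(
        rows, columns=["protein_id", "slice", "n_peptides", "deviation", "reliability"]
    )
    return ProfileSet(retained, profiles, reliab), details
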