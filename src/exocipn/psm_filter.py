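"""Target-decoy FDR filtering and technical-replicate merging of PSM tables.

A PSM (peptide-spectrum match) table is a tidy pandas DataFrame with one row
per matched spectrum.  The pipeline screens charge states at load time (2-6),
applies a precursor mass tolerance filter (default |error| <= 10 ppm,
inclusive), picks a discriminant-score threshold so that the decoy-estimated
false discovery rate of the accepted set is at most alpha (default 5%), and
finally aggregates the accepted target PSMs across technical replicates.

FDR here is the simple accepted-decoy / accepted-target ratio at PSM level:
the decoy database has the same size and score-generating law as the
incorrect-target population, so the count of accepted decoys estimates the
count of accepted false targets.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSM_COLUMNS = (
    "spectrum_id",
    "sample_id",
    "replicate_id",
    "timepoint",
    "peptide",
    "charge",
    "score",
    "is_decoy",
    "peak_area",
    "precursor_error_ppm",
)

MERGE_KEY = ["sample_id", "timepoint", "peptide", "charge"]

MIN_CHARGE, MAX_CHARGE = 2, 6

DEFAULT_PSM_ALPHA = 0.05
DEFAULT_MAX_PPM = 10.0


class UndefinedFdrError(ValueError):
    """Raised when an FDR is requested at a threshold accepting no targets."""


def validate_psms(psms: pd.DataFrame) -> pd.DataFrame:
    """Schema and range checks; drops out-of-range charge states with a log.

    Charge states outside [2, 6] are screened out (with a logged count)
    rather than raising, mirroring instrument-side charge screening.  Other
    violations (non-finite scores, negative peak areas) are hard errors.
    """
    missing = [c for c in PSM_COLUMNS if c not in psms.columns]
    if missing:
        raise ValueError(f"PSM table is missing column(s): {missing}")
    if not np.isfinite(psms["score"]).all():
        raise ValueError("PSM scores must be finite")
    if (psms["peak_area"] < 0).any():
        raise ValueError("peak_area must be >= 0")
    if not psms["is_decoy"].isin([0, 1]).all():
        raise ValueError("is_decoy must be 0/1")
    in_range = psms["charge"].between(MIN_CHARGE, MAX_CHARGE)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info(
            "dropped %d PSM(s) with charge outside [%d, %d]",
            n_dropped,
            MIN_CHARGE,
            MAX_CHARGE,
        )
        psms = psms.loc[in_range]
    return psms.reset_index(drop=True)


def tolerance_filter(
    psms: pd.DataFrame, max_ppm: float = DEFAULT_MAX_PPM
) -> pd.DataFrame:
    """Retain PSMs with |precursor_error_ppm| <= max_ppm (inclusive bound)."""
    if not max_ppm > 0:
        raise ValueError(f"max_ppm must be positive, got {max_ppm}")
    keep = psms["precursor_error_ppm"].abs() <= max_ppm
    return psms.loc[keep].reset_index(drop=True)


def estimate_fdr(psms: pd.DataFrame, threshold: float) -> float:
    """Decoy-estimated FDR of the set {score >= threshold}.

    Returns (#accepted decoys) / (#accepted targets).  Undefined (error) when
    no target reaches the threshold.
    """
    accepted = psms["score"] >= threshold
    n_target = int((accepted & (psms["is_decoy"] == 0)).sum())
    n_decoy = int((accepted & (psms["is_decoy"] == 1)).sum())
    if n_target == 0:
        raise UndefinedFdrError(
            f"no target PSM at or above threshold {threshold}"
        )
    return n_decoy / n_target


def filter_at_fdr(
    psms: pd.DataFrame, alpha: float = DEFAULT_PSM_ALPHA
) -> tuple[pd.DataFrame, float | None]:
    """Accept target PSMs at the largest set with decoy-estimated FDR <= alpha.

    The threshold is the smallest observed score t such that
    estimate_fdr(psms, t) <= alpha; because the accepted-target count grows as
    t decreases, this maximises the number of accepted targets.  Ties at the
    threshold are all accepted (acceptance is score >= t).  Decoys are
    discarded from the returned table.  If no threshold achieves alpha, an
    empty accepted set is returned with a warning, not an exception.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    scores = psms["score"].to_numpy(dtype=float)
    is_decoy = psms["is_decoy"].to_numpy() == 1
    if scores.size == 0:
        warnings.warn("empty PSM table: nothing to filter")
        return psms.iloc[0:0].copy(), None

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = is_decoy[order]
    cum_decoy = np.cumsum(d_sorted)
    cum_target = np.cumsum(~d_sorted)

    # Evaluate candidate thresholds at the last row of each tie block, where
    # the cumulative counts equal the counts of {score >= t}.
    last_of_block = np.append(s_sorted[1:] != s_sorted[:-1], True)
    idx = np.flatnonzero(last_of_block)
    n_t = cum_target[idx]
    n_d = cum_decoy[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1), np.inf)
    valid = (n_t > 0) & (fdr <= alpha)
    if not valid.any():
        warnings.warn(
            f"no score threshold attains FDR <= {alpha}; returning an empty "
            "accepted set"
        )
        return psms.iloc[0:0].copy(), None

    # Smallest valid threshold = deepest valid tie block.
    best = idx[np.flatnonzero(valid)[-1]]
    threshold = float(s_sorted[best])
    accepted = psms.loc[(psms["score"] >= threshold) & (psms["is_decoy"] == 0)]
    return accepted.reset_index(drop=True), threshold


def merge_replicates(psms: pd.DataFrame) -> pd.DataFrame:
    """Aggregate PSMs across technical replicates.

    Output has one row per (sample_id, timepoint, peptide, charge) with the
    total PSM count (the spectral contribution), the summed peak area, and
    the best score.  Duplicate spectrum ids within one replicate run would
    double-count spectra and are rejected.
    """
    if psms.empty:
        return pd.DataFrame(
            columns=MERGE_KEY + ["psm_count", "peak_area", "score"]
        )
    run_key = ["sample_id", "timepoint", "replicate_id", "spectrum_id"]
    dup = psms.duplicated(subset=run_key)
    if dup.any():
        example = psms.loc[dup, run_key].iloc[0].to_dict()
        raise ValueError(
            f"duplicate spectrum id within a replicate run: {example}"
        )
    merged = (
        psms.groupby(MERGE_KEY, sort=True, as_index=False)
        .agg(
            psm_count=("spectrum_id", "size"),
            peak_area=("peak_area", "sum"),
            score=("score", "max"),
        )
    )
    return merged


# ---------------------------------------------------------------------------
# TSV interface (round-trip exact)
# ---------------------------------------------------------------------------


def read_psm_table(path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(
        str(path),
        sep="\t",
        float_precision="round_trip",
        dtype={
            "spectrum_id": str,
            "sample_id": str,
            "replicate_id": np.int64,
            "timepoint": str,
            "peptide": str,
            "charge": np.int64,
            "score": float,
            "is_decoy": np.int64,
            "peak_area": float,
            "precursor_error_ppm": float,
        },
    )
    if validate:
        df = validate_psms(df)
    return df


def write_psm_table(psms: pd.DataFrame, path) -> None:
    # Floats are serialised with repr (pandas default), which round-trips
    # exactly, so read -> write is bit-identical.
    psms.loc[:, list(PSM_COLUMNS)].to_csv(str(path), sep="\t", index=False)
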