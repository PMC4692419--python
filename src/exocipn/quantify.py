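"""The two quantification tracks built from accepted, replicate-merged PSMs.

Track 1 (``protein_counts``): per protein group, the number of merged PSM
observations of its *group-unique* peptides — unique spectral counts.  PSMs
of peptides shared between groups are excluded entirely (contributing a
shared spectrum to several proteins would duplicate evidence).

Track 2 (``peptide_areas``): per unique peptide, the summed chromatographic
peak area (across charge states) in each sample.  Shared peptides are absent
from this track by construction.

A missing feature-in-sample observation is a zero, not an NA: spectral
counting has a natural zero and the downstream rank test tolerates ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import PeptideMapping

logger = logging.getLogger(__name__)

TRACK_PROTEIN = "protein_counts"
TRACK_PEPTIDE = "peptide_areas"

SAMPLE_KEY_SEP = ":"


def sample_key(sample_id: str, timepoint: str) -> str:
    """Column identifier for one (sample, timepoint) serum draw."""
    return f"{sample_id}{SAMPLE_KEY_SEP}{timepoint}"


@dataclass
class QuantMatrix:
    """Features x samples table for one quantification track.

    ``values`` is indexed by feature id (protein-group accession or peptide
    sequence); columns are sample keys ``<sample_id>:<timepoint>``.
    ``samples`` is indexed by the same keys with columns sample_id,
    timepoint, group.  ``normalized`` marks real-valued post-normalization
    matrices (otherwise protein counts must be non-negative integers).
    """

    track: str
    values: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.track not in (TRACK_PROTEIN, TRACK_PEPTIDE):
            raise ValueError(f"unknown track {self.track!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids in QuantMatrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample keys in QuantMatrix")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and samples index must match")
        missing = {"sample_id", "timepoint", "group"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"samples table is missing column(s): {missing}")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("QuantMatrix values must be non-negative")
        if not self.normalized:
            if self.track == TRACK_PROTEIN and not np.array_equal(
                arr, np.round(arr)
            ):
                raise ValueError("protein_counts values must be integers")
            if arr.size and (arr.sum(axis=1) == 0).any():
                raise ValueError("all-zero feature rows must be dropped")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def at_timepoint(self, timepoint: str) -> "QuantMatrix":
        keep = self.samples.index[self.samples["timepoint"] == timepoint]
        if len(keep) == 0:
            raise ValueError(f"no samples at timepoint {timepoint!r}")
        values = self.values.loc[:, keep]
        nonzero = values.sum(axis=1) > 0
        if self.normalized:
            nonzero[:] = True
        return QuantMatrix(
            track=self.track,
            values=values.loc[nonzero],
            samples=self.samples.loc[keep],
            normalized=self.normalized,
        )

    def subset_features(self, features: Sequence[str]) -> "QuantMatrix":
        missing = [f for f in features if f not in self.values.index]
        if missing:
            raise ValueError(f"unknown feature(s): {missing[:5]}")
        return replace(self, values=self.values.loc[list(features)])


def _sample_table(
    merged_psms: pd.DataFrame, sample_groups: Mapping[str, str]
) -> pd.DataFrame:
    pairs = (
        merged_psms[["sample_id", "timepoint"]]
        .drop_duplicates()
        .sort_values(["sample_id", "timepoint"])
    )
    missing = sorted(set(pairs["sample_id"]) - set(sample_groups))
    if missing:
        raise ValueError(f"no group label for sample(s): {missing[:5]}")
    keys = [
        sample_key(s, t) for s, t in zip(pairs["sample_id"], pairs["timepoint"])
    ]
    return pd.DataFrame(
        {
            "sample_id": list(pairs["sample_id"]),
            "timepoint": list(pairs["timepoint"]),
            "group": [sample_groups[s] for s in pairs["sample_id"]],
        },
        index=pd.Index(keys, name="sample_key"),
    )


def _unique_parent_lookup(
    mapping: Sequence[PeptideMapping],
) -> tuple[dict[str, str], set[str]]:
    """peptide -> sole parent group for unique peptides; set of known peptides."""
    unique_parent: dict[str, str] = {}
    known: set[str] = set()
    for m in mapping:
        known.add(m.peptide)
        if m.is_unique:
            (parent,) = m.parents
            unique_parent[m.peptide] = parent
    return unique_parent, known


def _check_known(peptides: pd.Series, known: set[str]) -> None:
    unknown = sorted(set(peptides) - known)
    if unknown:
        raise ValueError(
            f"PSM peptide(s) absent from the peptide mapping: {unknown[:5]}"
        )


def _pivot(
    long: pd.DataFrame,
    feature_col: str,
    value_col: str,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    wide = (
        long.pivot_table(
            index=feature_col,
            columns="sample_key",
            values=value_col,
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=samples.index, fill_value=0)
        .sort_index()
    )
    wide.columns.name = None
    n_zero = int((wide.sum(axis=1) == 0).sum())
    if n_zero:
        logger.info("dropping %d all-zero feature row(s)", n_zero)
        wide = wide.loc[wide.sum(axis=1) > 0]
    return wide


def build_protein_matrix(
    merged_psms: pd.DataFrame,
    mapping: Sequence[PeptideMapping],
    sample_groups: Mapping[str, str],
) -> QuantMatrix:
    """Unique spectral counts per protein group and sample.

    Each merged PSM observation of a group-unique peptide contributes its
    PSM count to the owning protein group; observations of shared peptides
    contribute to no protein at all.
    """
    unique_parent, known = _unique_parent_lookup(mapping)
    _check_known(merged_psms["peptide"], known)
    samples = _sample_table(merged_psms, sample_groups)

    rows = merged_psms.loc[merged_psms["peptide"].isin(unique_parent)].copy()
    rows["feature"] = rows["peptide"].map(unique_parent)
    rows["sample_key"] = [
        sample_key(s, t) for s, t in zip(rows["sample_id"], rows["timepoint"])
    ]
    wide = _pivot(rows, "feature", "psm_count", samples).astype(np.int64)
    return QuantMatrix(track=TRACK_PROTEIN, values=wide, samples=samples)


def build_peptide_matrix(
    merged_psms: pd.DataFrame,
    mapping: Sequence[PeptideMapping],
    sample_groups: Mapping[str, str],
) -> QuantMatrix:
    """Summed peak areas per unique peptide (across charge states) and sample."""
    unique_parent, known = _unique_parent_lookup(mapping)
    _check_known(merged_psms["peptide"], known)
    samples = _sample_table(merged_psms, sample_groups)

    rows = merged_psms.loc[merged_psms["peptide"].isin(unique_parent)].copy()
    rows["sample_key"] = [
        sample_key(s, t) for s, t in zip(rows["sample_id"], rows["timepoint"])
    ]
    wide = _pivot(rows.rename(columns={"peptide": "feature"}),
                  "feature", "peak_area", samples).astype(float)
    return QuantMatrix(track=TRACK_PEPTIDE, values=wide, samples=samples)


def roll_up_peptides(
    peptide_results: pd.DataFrame,
    mapping: Sequence[PeptideMapping],
) -> pd.DataFrame:
    """Aggregate per-peptide test results to protein groups (best evidence).

    A protein group is represented by the minimum q over its unique peptides;
    its direction is taken from that best peptide.  Selection at any q
    threshold can then be read off the aggregated q values, so a protein is
    reported iff at least one of its unique peptides passes — set semantics,
    no double counting.
    """
    required = {"feature", "p_value", "q_value", "direction"}
    missing = required - set(peptide_results.columns)
    if missing:
        raise ValueError(f"peptide results missing column(s): {missing}")
    unique_parent, _ = _unique_parent_lookup(mapping)
    unknown = sorted(set(peptide_results["feature"]) - set(unique_parent))
    if unknown:
        raise ValueError(
            f"peptide(s) without a unique parent in the mapping: {unknown[:5]}"
        )
    df = peptide_results.copy()
    df["protein"] = df["feature"].map(unique_parent)
    df = df.sort_values(["q_value", "p_value", "feature"], kind="stable")
    best = df.groupby("protein", sort=True).first().reset_index()
    out = best.rename(columns={"feature": "best_peptide"})[
        ["protein", "best_peptide", "p_value", "q_value", "direction"]
    ]
    return out.rename(columns={"protein": "feature"})


# ---------------------------------------------------------------------------
# TSV interface (round-trip exact)
# ---------------------------------------------------------------------------


def write_quant_matrix(qm: QuantMatrix, values_path, samples_path) -> None:
    values = qm.values.copy()
    values.index.name = "feature"
    values.to_csv(str(values_path), sep="\t")
    samples = qm.samples.copy()
    samples.index.name = "sample_key"
    samples.to_csv(str(samples_path))


def read_quant_matrix(
    track: str, values_path, samples_path, normalized: bool = False
) -> QuantMatrix:
    values = pd.read_csv(
        str(values_path), sep="\t", index_col="feature",
        float_precision="round_trip",
    )
    values.index.name = None
    if track == TRACK_PROTEIN and not normalized:
        values = values.astype(np.int64)
    samples = pd.read_csv(str(samples_path), index_col="sample_key", dtype=str)
    samples.index.name = "sample_key"
    return QuantMatrix(
        track=track, values=values, samples=samples, normalized=normalized
    )
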