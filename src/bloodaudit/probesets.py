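"""Probe filtering, probe-set construction and summarization.

Rebuilds transcript-level probe-sets from a probe/genome alignment table
and a probe intensity matrix: keep probes with a unique genomic match,
drop probes that have BOTH very low signal AND a low coefficient of
variation, group surviving probes by transcript (at least ``min_probes``
per set), summarize each set as the median of its member probes' log2
intensities, then median-scale normalize and variance-filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProbeSetDefinition",
    "filter_unique_probes",
    "filter_uninformative_probes",
    "build_probesets",
    "summarize_probesets",
    "normalize_median_scale",
    "filter_expressed_sd",
]


@dataclass
class ProbeSetDefinition:
    """Transcript-keyed probe-sets: probeset_id -> ordered probe ids."""

    probes: dict[str, list[str]]
    annotation: dict[str, tuple[str, str]]  # probeset_id -> (transcript_id, gene_symbol)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, members in self.probes.items():
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"probe(s) {sorted(overlap)[:3]} assigned to multiple probe-sets")
            seen.update(members)

    def __len__(self) -> int:
        return len(self.probes)

    def to_frame(self) -> pd.DataFrame:
        """Flat CDF-like map: one (probeset_id, probe_id) row per member probe."""
        rows = [(ps, pr) for ps, members in self.probes.items() for pr in members]
        return pd.DataFrame(rows, columns=["probeset_id", "probe_id"])


def filter_unique_probes(alignments: pd.DataFrame) -> pd.DataFrame:
    """Retain exactly the probes with a single genomic match."""
    if alignments.empty:
        raise ValueError("alignment table is empty")
    return alignments[alignments["n_genomic_matches"] == 1].copy()


def filter_uninformative_probes(
    intensities: pd.DataFrame,
    signal_quantile: float = 0.1,
    cv_threshold: float = 0.05,
) -> set:
    """Drop probes with BOTH very low signal AND a low coefficient of variation.

    A probe is removed iff its mean linear intensity is below the
    ``signal_quantile`` quantile of all probe means AND its CV (sd/mean)
    is below ``cv_threshold``. The conjunction matters: a quiet but
    variable probe, or a bright flat probe, is kept.

    Returns the set of retained probe ids.
    """
    if intensities.shape[1] < 2:
        raise ValueError("coefficient of variation undefined with a single sample")
    means = intensities.mean(axis=1)
    sds = intensities.std(axis=1, ddof=1)
    cv = sds / means.replace(0.0, np.nan)
    cv = cv.fillna(0.0)
    signal_cut = means.quantile(signal_quantile)
    removed = (means < signal_cut) & (cv < cv_threshold)
    return set(intensities.index[~removed])


def build_probesets(
    alignments: pd.DataFrame,
    retained_probes: set,
    min_probes: int = 3,
) -> ProbeSetDefinition:
    """Group surviving probes into one probe-set per transcript.

    Transcripts with fewer than ``min_probes`` surviving probes contribute
    no probe-set.
    """
    surviving = alignments[alignments["probe_id"].isin(retained_probes)]
    probes: dict[str, list[str]] = {}
    annotation: dict[str, tuple[str, str]] = {}
    for tid, grp in surviving.groupby("transcript_id", sort=True):
        if len(grp) < min_probes:
            continue
        probes[tid] = grp["probe_id"].tolist()
        annotation[tid] = (tid, grp["gene_symbol"].iloc[0])
    return ProbeSetDefinition(probes, annotation)


def summarize_probesets(
    intensities: pd.DataFrame,
    definition: ProbeSetDefinition,
) -> pd.DataFrame:
    """Summarize each probe-set as the median of member probes' log2 intensities."""
    missing = [p for members in definition.probes.values()
               for p in members if p not in intensities.index]
    if missing:
        raise ValueError(f"probes in definition absent from intensity matrix: {missing[:5]}")
    log2 = np.log2(intensities + 1.0)
    rows = {ps: log2.loc[members].median(axis=0) for ps, members in definition.probes.items()}
    out = pd.DataFrame(rows).T
    out.index.name = "probeset_id"
    return out


def normalize_median_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shift each sample column so its median equals the global median of column medians."""
    col_medians = matrix.median(axis=0)
    target = col_medians.median()
    return matrix - col_medians + target


def filter_expressed_sd(matrix: pd.DataFrame, sd_threshold: float) -> pd.DataFrame:
    """Keep rows whose across-sample standard deviation is >= sd_threshold."""
    if matrix.shape[1] < 2:
        raise ValueError("standard deviation filter needs at least 2 samples")
    sds = matrix.std(axis=1, ddof=1)
    return matrix[sds >= sd_threshold]
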