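"""Subtraction-based normalization of log2 tiling-array signals.

Three normalizations are supported, all probe-local (no quantile or
scale normalization between arrays):

* ChIP enrichment: per replicate pair, log2(IP) − log2(input), then the
  arithmetic mean over biological replicates.
* H3K36me3 corrected for nucleosome density: K36 enrichment minus H3
  enrichment, probe-wise (a log-scale ratio).
* FAIRE: mean FAIRE signal minus the mean of the genomic-DNA
  hybridizations, which corrects GC-dependent hybridization bias.

Probes missing (NA) in any contributing array are dropped from the
output track, with the dropped count logged — silent imputation would
bias the bulk intron/exon comparisons downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPERIMENTS = ("polII_ip", "input", "h3_ip", "k36_ip", "faire", "gdna")


class ProbeSetMismatch(ValueError):
    """Arrays in one analysis must share an identical probe-id set."""


@dataclass
class SignalArray:
    """Raw log2 intensities of one hybridization (one array)."""

    experiment: str
    replicate_id: str
    values: pd.Series  # index: probe_id, values: log2 intensity

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        self.values = pd.Series(self.values, dtype=float)
        finite = np.isfinite(self.values.dropna().to_numpy())
        if not finite.all():
            raise ValueError(
                f"{self.experiment}/{self.replicate_id}: non-finite signal values"
            )


@dataclass
class EnrichmentTrack:
    """Per-probe normalized log2 enrichment for one experiment."""

    name: str
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)


def _check_probe_sets(arrays: Sequence[pd.Series]) -> pd.Index:
    ref = arrays[0].index
    for other in arrays[1:]:
        if not ref.equals(other.index):
            diff = len(ref.symmetric_difference(other.index))
            raise ProbeSetMismatch(
                f"probe sets differ between arrays (symmetric difference: {diff} probes)"
            )
    return ref


def _drop_na(values: pd.Series, context: str) -> pd.Series:
    n_na = int(values.isna().sum())
    if n_na:
        logger.info("%s: dropping %d probe(s) with missing values", context, n_na)
        values = values.dropna()
    return values


def subtract_input(ip_reps: Sequence[SignalArray], input_reps: Sequence[SignalArray],
                   name: str = "polII") -> EnrichmentTrack:
    """Per replicate pair IP − input, then mean over replicate pairs.

    Replicates are paired positionally; the number of IP and input arrays
    must match.
    """
    if not ip_reps or len(ip_reps) != len(input_reps):
        raise ValueError(
            f"need equal, nonzero replicate counts (got {len(ip_reps)} IP, "
            f"{len(input_reps)} input)"
        )
    _check_probe_sets([a.values for a in ip_reps] + [a.values for a in input_reps])
    per_pair = [ip.values - inp.values for ip, inp in zip(ip_reps, input_reps)]
    mean = pd.concat(per_pair, axis=1).mean(axis=1, skipna=False)
    return EnrichmentTrack(name=name, values=_drop_na(mean, f"subtract_input[{name}]"))


def normalize_k36_by_h3(k36: EnrichmentTrack, h3: EnrichmentTrack) -> EnrichmentTrack:
    """H3K36me3 enrichment corrected for histone H3 density: k36 − h3 probe-wise."""
    _check_probe_sets([k36.values, h3.values])
    out = k36.values - h3.values
    return EnrichmentTrack(name="k36_norm", values=_drop_na(out, "normalize_k36_by_h3"))


def normalize_faire(faire_reps: Sequence[SignalArray],
                    gdna_reps: Sequence[SignalArray]) -> EnrichmentTrack:
    """Mean FAIRE signal minus mean genomic-DNA signal, probe-wise."""
    if not faire_reps or not gdna_reps:
        raise ValueError("need at least one FAIRE and one gDNA replicate")
    _check_probe_sets([a.values for a in faire_reps] + [a.values for a in gdna_reps])
    faire_mean = pd.concat([a.values for a in faire_reps], axis=1).mean(axis=1, skipna=False)
    gdna_mean = pd.concat([a.values for a in gdna_reps], axis=1).mean(axis=1, skipna=False)
    return EnrichmentTrack(name="faire", values=_drop_na(faire_mean - gdna_mean, "normalize_faire"))


def read_signal_tsv(path, experiment: str, replicate_id: str) -> SignalArray:
    """Read one per-array signal TSV with header ``probe_id  value``."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if list(df.columns[:2]) != ["probe_id", "value"]:
        raise ValueError(f"signal TSV header must be probe_id/value, got {list(df.columns)}")
    values = pd.Series(df["value"].to_numpy(float), index=pd.Index(df["probe_id"], name="probe_id"))
    return SignalArray(experiment=experiment, replicate_id=replicate_id, values=values)


def write_signal_tsv(array: SignalArray, path) -> None:
    df = pd.DataFrame({"probe_id": array.values.index, "value": array.values.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
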