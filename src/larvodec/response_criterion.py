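"""Probabilistic response criterion, reliability matrix and summary stats.

A trial counts as a *response* when the stimulation firing rate changes by
at least ``threshold_hz`` (default 5 Hz) relative to the extremes of the
spontaneous activity observed in that neuron over the ten seconds before
the stimulus: excitation when ``stim >= max(spont) + threshold``,
inhibition when ``stim <= min(spont) - threshold`` (boundaries inclusive).

Reliability of a (neuron, odor) pair is the fraction of its trials that
pass the criterion; the per-pair reliabilities form the response matrix
that defines which neurons are treated as *responding* to which odor in
the decoder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_data import Dataset, TrialRecord

logger = logging.getLogger(__name__)

EXCITATION = "excitation"
INHIBITION = "inhibition"
NONE = "none"


@dataclass(frozen=True)
class ResponseCall:
    """Criterion verdict for one trial. ``delta`` is the signed rate change
    (Hz) relative to the spontaneous extreme the call was made against."""

    neuron_id: str
    odor_id: str
    trial_index: Optional[int]
    call: str
    delta: float


def call_response(trial: TrialRecord, threshold_hz: float = 5.0) -> ResponseCall:
    """Classify one trial as excitation / inhibition / none.

    For non-responses ``delta`` is the rate change relative to the nearer
    exceeded spontaneous extreme, or 0 if the stimulation rate lies inside
    the spontaneous range.
    """
    hi = max(trial.spont_bins)
    lo = min(trial.spont_bins)
    stim = trial.stim_count
    if stim >= hi + threshold_hz:
        call, delta = EXCITATION, stim - hi
    elif stim <= lo - threshold_hz:
        call, delta = INHIBITION, stim - lo
    elif stim > hi:
        call, delta = NONE, stim - hi
    elif stim < lo:
        call, delta = NONE, stim - lo
    else:
        call, delta = NONE, 0.0
    return ResponseCall(trial.neuron_id, trial.odor_id, trial.trial_index, call, float(delta))


@dataclass(frozen=True)
class ReliabilityCell:
    n_trials: int
    fraction: float
    sign: str  # dominant sign among responding trials; NONE if fraction == 0


class ReliabilityMatrix:
    """Per-(neuron, odor) response reliability with dominant sign."""

    def __init__(self, cells: Dict[tuple, ReliabilityCell], neuron_ids, odor_ids):
        self.cells = cells
        self.neuron_ids = tuple(neuron_ids)
        self.odor_ids = tuple(odor_ids)

    def fractions(self) -> pd.DataFrame:
        """Neurons as rows, odors as columns; NaN where a pair has no trials."""
        df = pd.DataFrame(np.nan, index=list(self.neuron_ids), columns=list(self.odor_ids))
        for (n, o), cell in self.cells.items():
            df.loc[n, o] = cell.fraction
        return df

    def signs(self) -> pd.DataFrame:
        df = pd.DataFrame("", index=list(self.neuron_ids), columns=list(self.odor_ids))
        for (n, o), cell in self.cells.items():
            df.loc[n, o] = cell.sign
        return df

    def responding_set(self, min_fraction: float = 0.0) -> Dict[str, FrozenSet[str]]:
        """Map each odor to the neurons deemed responding to it.

        With the default ``min_fraction`` of 0, any pair with at least one
        trial above criterion is included; a positive cutoff requires
        ``fraction >= min_fraction``.
        """
        out: Dict[str, set] = {o: set() for o in self.odor_ids}
        for (n, o), cell in self.cells.items():
            if cell.fraction > 0 and cell.fraction >= min_fraction:
                out[o].add(n)
        return {o: frozenset(v) for o, v in out.items()}

    def to_csv(self, path) -> None:
        self.fractions().to_csv(path, index_label="neuron_id")


def reliability_matrix(ds: Dataset, threshold_hz: float = 5.0) -> ReliabilityMatrix:
    """Fraction of trials above criterion for every (neuron, odor) pair.

    Pairs with zero trials are excluded (logged). The dominant sign is the
    majority sign among responding trials; ties go to excitation with a
    logged warning.
    """
    cells = {}
    for n in ds.neuron_ids:
        for o in ds.odor_ids:
            trials = ds.trials_for(n, o)
            if not trials:
                logger.info("pair (%s, %s) has no trials; excluded", n, o)
                continue
            calls = [call_response(t, threshold_hz) for t in trials]
            n_exc = sum(c.call == EXCITATION for c in calls)
            n_inh = sum(c.call == INHIBITION for c in calls)
            n_resp = n_exc + n_inh
            if n_resp == 0:
                sign = NONE
            elif n_exc > n_inh:
                sign = EXCITATION
            elif n_inh > n_exc:
                sign = INHIBITION
            else:
                logger.warning(
                    "pair (%s, %s): tie between excitatory and inhibitory calls; "
                    "reporting excitation",
                    n,
                    o,
                )
                sign = EXCITATION
            cells[(n, o)] = ReliabilityCell(len(trials), n_resp / len(trials), sign)
    return ReliabilityMatrix(cells, ds.neuron_ids, ds.odor_ids)


def responding_set_from_csv(path, min_fraction: float = 0.0) -> Dict[str, FrozenSet[str]]:
    """Rebuild a responding set from a reliability CSV written by
    :meth:`ReliabilityMatrix.to_csv`."""
    df = pd.read_csv(path, index_col="neuron_id")
    out: Dict[str, set] = {o: set() for o in df.columns}
    for n, row in df.iterrows():
        for o, frac in row.items():
            if pd.notna(frac) and frac > 0 and frac >= min_fraction:
                out[o].add(str(n))
    return {o: frozenset(v) for o, v in out.items()}


def _summary(values: Sequence[float]) -> dict:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return {"mean": np.nan, "se": np.nan, "n": 0, "min": np.nan, "max": np.nan}
    se = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else np.nan
    return {
        "mean": float(x.mean()),
        "se": se,
        "n": int(x.size),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def summarize_activity(ds: Dataset, threshold_hz: float = 5.0) -> pd.DataFrame:
    """Per-neuron activity summary in the style of a recording overview
    table: spontaneous rates (the second before each stimulation),
    stimulation rates, and above-criterion response deltas. Columns are
    ``<block>_<stat>`` with blocks ``spont``, ``stim``, ``resp``."""
    rows = []
    for n in ds.neuron_ids:
        trials = [t for t in ds.trials if t.neuron_id == n]
        spont = [t.spont_last for t in trials]
        stim = [t.stim_count for t in trials]
        deltas = [
            c.delta for c in (call_response(t, threshold_hz) for t in trials) if c.call != NONE
        ]
        row = {"neuron_id": n}
        for block, vals in (("spont", spont), ("stim", stim), ("resp", deltas)):
            for stat, v in _summary(vals).items():
                row[f"{block}_{stat}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("neuron_id")


def pearson_with_df(x: Sequence[float], y: Sequence[float]) -> Tuple[float, int, float]:
    """Pearson correlation with its degrees of freedom (n - 2) and the
    two-sided p-value from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), int(x.size - 2), float(p)
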