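"""Assay statistics: spike density, excited-neuron ratio, transfer accuracy,
and repeat-level summaries (mean +/- SEM, one-way ANOVA).

Spike density is the whole-network spike count per millisecond over a
window (baseline window 100-200 ms, persistent-activity window 200-300 ms
by default).  The excited-neuron ratio is the percentage of stimulated
neurons whose spike count rises by at least 50% from the pre- to the
post-stimulus window.  Transfer accuracy is the pixelwise agreement (in %)
between the binary input image and the decoded output image of the 900
L2/3 pyramidal cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .stimulus import BinaryPattern, N_PIXELS

__all__ = [
    "spike_density",
    "excited_ratio",
    "transfer_accuracy",
    "summarize",
    "GroupSummary",
    "significance_stars",
]


def spike_density(raster, interval: tuple[float, float]) -> float:
    """Whole-network spikes per ms in the half-open interval [t0, t1)."""
    t0, t1 = interval
    if not t1 > t0:
        raise ValueError(f"degenerate interval {interval}")
    return raster.count_in(t0, t1) / (t1 - t0)


def excited_ratio(
    raster,
    stimulated: Iterable[int],
    pre: tuple[float, float] = (100.0, 200.0),
    post: tuple[float, float] = (200.0, 300.0),
) -> float:
    """Percentage of stimulated neurons in an excited state.

    A neuron is excited when its spike count in the post window exceeds its
    pre-window count by at least 50% (and strictly increases, so a neuron
    silent in both windows is not excited; one silent before the stimulus
    is excited as soon as it fires at all).  Pre and post windows must have
    equal length so counts compare as rates.
    """
    ids = np.array(sorted(set(stimulated)), dtype=np.int64)
    if len(ids) == 0:
        raise ValueError("empty stimulated set")
    if abs((pre[1] - pre[0]) - (post[1] - post[0])) > 1e-9:
        raise ValueError("pre and post windows must have equal length")
    n = int(raster.neuron_ids.max(initial=0))
    n = max(n, int(ids.max()))
    c_pre = raster.counts_per_neuron(*pre, n)[ids]
    c_post = raster.counts_per_neuron(*post, n)[ids]
    excited = (c_post >= 1.5 * c_pre) & (c_post > c_pre)
    return 100.0 * float(np.count_nonzero(excited)) / len(ids)


def transfer_accuracy(input_pattern: BinaryPattern, output_pattern: BinaryPattern) -> float:
    """Pixelwise agreement of two 30x30 binary images, in percent.

    Counts both agreement cases — ON pixels whose neuron fired and OFF
    pixels whose neuron stayed silent — i.e. 100 * (1 - Hamming/900).
    """
    agree = N_PIXELS - input_pattern.hamming(output_pattern)
    return 100.0 * agree / N_PIXELS


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float


def significance_stars(p: float) -> str:
    """The reporting convention used throughout: * p<0.05, ** p<0.01,
    *** p<0.0001, ns otherwise."""
    if p < 0.0001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize(
    values: Sequence[float] | Mapping[str, Sequence[float]],
    groups: Sequence[str] | None = None,
) -> tuple[Dict[str, GroupSummary], float, float]:
    """Per-group mean and SEM plus a one-way ANOVA across groups.

    Accepts either a mapping {group: values} or parallel value/label
    sequences.  Returns (summaries, F, p); with fewer than two groups the
    ANOVA outputs are NaN.  SEM uses the sample standard deviation
    (ddof=1) over the repeats of a group.
    """
    if isinstance(values, Mapping):
        by_group = {str(k): np.asarray(v, dtype=float) for k, v in values.items()}
    else:
        if groups is None or len(groups) != len(values):
            raise ValueError("values and groups must be parallel sequences")
        by_group = {}
        for v, g in zip(values, groups):
            by_group.setdefault(str(g), []).append(float(v))
        by_group = {k: np.asarray(v) for k, v in by_group.items()}

    summaries: Dict[str, GroupSummary] = {}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations for a SEM")
        summaries[g] = GroupSummary(
            group=g, n=len(v), mean=float(v.mean()), sem=float(v.std(ddof=1) / np.sqrt(len(v)))
        )
    if len(by_group) >= 2:
        arrays = list(by_group.values())
        if np.ptp(np.concatenate(arrays)) == 0:
            # all observations identical across groups: no variance anywhere
            f_stat, p_val = 0.0, 1.0
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p_val = stats.f_oneway(*arrays)
            f_stat, p_val = float(f_stat), float(p_val)
    else:
        f_stat, p_val = float("nan"), float("nan")
    return summaries, f_stat, p_val
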