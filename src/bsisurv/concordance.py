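"""Harrell's concordance index for right-censored survival data.

The C-index is the fraction of usable patient pairs in which the patient
with the higher predicted risk experienced the event first. A pair (i, j)
is usable when ``time_i < time_j`` and patient i's event was observed —
then we know i genuinely outlived by less. Pairs with exactly tied times
are excluded (strict Harrell convention); tied risk scores count 1/2.

0.5 is chance level, 1.0 perfect risk ranking, 0.0 perfect anti-ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConcordanceUndefined(ValueError):
    """No usable pair exists (e.g. all patients censored)."""


@dataclass(frozen=True)
class CIndexValue:
    """A concordance value with its pair bookkeeping."""

    value: float
    concordant_pairs: int
    tied_pairs: int
    usable_pairs: int

    def __float__(self) -> float:
        return self.value


def c_index(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> CIndexValue:
    """Compute Harrell's C for risk scores against observed survival.

    Parameters
    ----------
    risk:
        Predicted risk scores; higher = expected to die sooner.
    time:
        Observed follow-up times.
    event:
        1 if the event (death) was observed at ``time``, 0 if censored.

    Raises
    ------
    ConcordanceUndefined
        If no usable pair exists.
    """
    risk = np.asarray(risk, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).astype(int).ravel()
    n = risk.shape[0]
    if not (time.shape[0] == n and event.shape[0] == n):
        raise ValueError("risk, time and event must have equal length")
    if n < 2:
        raise ConcordanceUndefined("need at least two patients")

    order = np.argsort(time, kind="stable")
    t = time[order]
    r = risk[order]
    e = event[order]

    concordant = 0
    tied = 0
    usable = 0
    # i ranges over observed events; usable partners are all j with t_j > t_i.
    ev_idx = np.nonzero(e == 1)[0]
    # first index with time strictly greater than t[i]
    upper = np.searchsorted(t, t[ev_idx], side="right")
    for i, start in zip(ev_idx, upper, strict=True):
        if start >= n:
            continue
        rj = r[start:]
        usable += rj.shape[0]
        concordant += int(np.count_nonzero(r[i] > rj))
        tied += int(np.count_nonzero(r[i] == rj))
    if usable == 0:
        raise ConcordanceUndefined("no usable pairs (check censoring and tied times)")
    value = (concordant + 0.5 * tied) / usable
    return CIndexValue(
        value=float(value),
        concordant_pairs=int(concordant),
        tied_pairs=int(tied),
        usable_pairs=int(usable),
    )


def c_statistic(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Bare C-index value; 0.5 when undefined only by all-tied risks is NOT
    special-cased — callers wanting a fallback catch :class:`ConcordanceUndefined`."""
    return c_index(risk, time, event).value
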