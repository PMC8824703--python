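"""Equal-variance Gaussian signal-detection measures.

Yes/no discrimination outcomes are summarised per observer and phase as
hit rate H (signal trials answered "yes") and false-alarm rate F (noise
trials answered "yes"), with extreme rates corrected by the 0.5/n rule
before z-transforming:

    d' = z(H) - z(F)          sensitivity
    C  = -(z(H) + z(F)) / 2   criterion (negative = liberal)
    beta = exp(d' * C)        likelihood ratio at the criterion

Outcomes are always computed per participant and only then aggregated;
group-level rates are never pooled into a group d'.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy.special import ndtri


@dataclass(frozen=True)
class OutcomeCounts:
    """Raw yes/no counts for one observer x phase x condition."""

    n_signal: int
    n_noise: int
    hits: int
    false_alarms: int

    def __post_init__(self) -> None:
        if self.n_signal < 1 or self.n_noise < 1:
            raise ValueError("need at least one signal and one noise trial")
        if not 0 <= self.hits <= self.n_signal:
            raise ValueError("hits must lie in [0, n_signal]")
        if not 0 <= self.false_alarms <= self.n_noise:
            raise ValueError("false_alarms must lie in [0, n_noise]")


@dataclass(frozen=True)
class SDTOutcome:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float
    beta: float

    def __post_init__(self) -> None:
        if not (0 < self.hit_rate < 1 and 0 < self.fa_rate < 1):
            raise ValueError("corrected rates must lie strictly inside (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if abs(self.beta - math.exp(self.d_prime * self.criterion_c)) > 1e-9 * max(1.0, self.beta):
            raise ValueError("beta inconsistent with exp(d' * C)")


def correct_rate(successes: int, n: int) -> float:
    """Extreme-rate correction: 0 -> 0.5/n, n -> (n-0.5)/n, else successes/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if successes == 0:
        return 0.5 / n
    if successes == n:
        return (n - 0.5) / n
    return successes / n


def sdt_outcome(counts: OutcomeCounts) -> SDTOutcome:
    """d', C and beta from raw counts, with extreme-rate correction."""
    h = correct_rate(counts.hits, counts.n_signal)
    f = correct_rate(counts.false_alarms, counts.n_noise)
    zh = float(ndtri(h))
    zf = float(ndtri(f))
    d = zh - zf
    c = -(zh + zf) / 2.0
    return SDTOutcome(hit_rate=h, fa_rate=f, d_prime=d, criterion_c=c,
                      beta=math.exp(d * c))


def change_scores(pre: SDTOutcome, post: SDTOutcome) -> dict[str, float]:
    """Post-minus-pre deltas of d', C and beta for one observer."""
    return {
        "delta_d_prime": post.d_prime - pre.d_prime,
        "delta_criterion_c": post.criterion_c - pre.criterion_c,
        "delta_beta": post.beta - pre.beta,
    }


def outcomes_from_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long-format response table into per-cell SDT outcomes.

    ``responses`` needs columns participant, phase, kind
    ('intelligible' = signal, 'unintelligible' = noise), said_speech (bool),
    and optionally condition.  Returns one row per participant x phase
    (x condition) with H, F, d_prime, C, beta.
    """
    required = {"participant", "phase", "kind", "said_speech"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    keys = ["participant", "phase"] + (
        ["condition"] if "condition" in responses.columns else []
    )
    rows = []
    for key, grp in responses.groupby(keys, sort=True):
        sig = grp[grp["kind"] == "intelligible"]
        noi = grp[grp["kind"] == "unintelligible"]
        counts = OutcomeCounts(
            n_signal=len(sig), n_noise=len(noi),
            hits=int(sig["said_speech"].sum()),
            false_alarms=int(noi["said_speech"].sum()),
        )
        out = sdt_outcome(counts)
        rows.append(dict(zip(keys, key if isinstance(key, tuple) else (key,)))
                    | {"H": out.hit_rate, "F": out.fa_rate,
                       "d_prime": out.d_prime, "C": out.criterion_c,
                       "beta": out.beta})
    return pd.DataFrame(rows)


def sdt_outcome_arrays(hits, n_signal, false_alarms, n_noise):
    """Vectorised d'/C/beta for arrays of counts (used in large simulations)."""
    hits = np.asarray(hits, dtype=float)
    fas = np.asarray(false_alarms, dtype=float)
    ns = np.asarray(n_signal, dtype=float)
    nn = np.asarray(n_noise, dtype=float)
    h = np.where(hits == 0, 0.5 / ns, np.where(hits == ns, (ns - 0.5) / ns, hits / ns))
    f = np.where(fas == 0, 0.5 / nn, np.where(fas == nn, (nn - 0.5) / nn, fas / nn))
    zh, zf = ndtri(h), ndtri(f)
    d = zh - zf
    c = -(zh + zf) / 2.0
    return d, c, np.exp(d * c)
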