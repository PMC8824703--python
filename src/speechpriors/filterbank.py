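"""Cochlear-position filterbank construction.

Band edges are spaced at equal basilar-membrane distance using the Greenwood
frequency–position function

    F(x) = A * (10**(a*x) - k),   x in [0, 1]

with the standard human constants A=165.4 Hz, a=2.1, k=0.88 (position x
normalised so that x=0 is the apex and x=1 the base of the cochlea).  Bands
are contiguous sixth-order Butterworth bandpass definitions between 100 and
5000 Hz, the configuration used for sine-vocoding degraded-speech stimuli.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class GreenwoodMap:
    """Greenwood frequency–position map with position normalised to [0, 1].

    Parameters
    ----------
    A : float
        Scale constant in Hz.
    a : float
        Exponent constant (per unit normalised position).
    k : float
        Integration constant; 0 <= k < 1 keeps F(0) > 0.
    """

    A: float = 165.4
    a: float = 2.1
    k: float = 0.88

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.a > 0 and 0 <= self.k < 1):
            raise ValueError(
                "GreenwoodMap requires A > 0, a > 0 and 0 <= k < 1 "
                f"(got A={self.A}, a={self.a}, k={self.k})"
            )

    @property
    def f_min(self) -> float:
        """Frequency at position 0 (apex)."""
        return self.A * (1.0 - self.k)

    @property
    def f_max(self) -> float:
        """Frequency at position 1 (base)."""
        return self.A * (10.0 ** self.a - self.k)


HUMAN_MAP = GreenwoodMap()


def greenwood_frequency(x, gmap: GreenwoodMap = HUMAN_MAP):
    """Map normalised basilar-membrane position to frequency in Hz."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("position must lie in [0, 1]")
    out = gmap.A * (10.0 ** (gmap.a * x) - gmap.k)
    return float(out) if out.ndim == 0 else out


def greenwood_position(f, gmap: GreenwoodMap = HUMAN_MAP):
    """Inverse Greenwood map: frequency in Hz to normalised position.

    Raises
    ------
    ValueError
        If ``f`` lies outside [F(0), F(1)] for this map.
    """
    f = np.asarray(f, dtype=float)
    lo, hi = gmap.f_min, gmap.f_max
    if np.any(f < lo) or np.any(f > hi):
        raise ValueError(
            f"frequency outside the map's range [{lo:.3f}, {hi:.3f}] Hz"
        )
    out = np.log10(f / gmap.A + gmap.k) / gmap.a
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FilterbankSpec:
    """Contiguous bandpass filterbank on the Greenwood map.

    ``edges`` holds ``n_bands + 1`` strictly increasing band-edge frequencies;
    adjacent bands share exactly one edge.  ``centers`` are the band midpoints
    in *position* space mapped back to Hz, consistent with the equal-distance
    spacing principle.
    """

    n_bands: int
    f_lo: float
    f_hi: float
    edges: tuple[float, ...]
    centers: tuple[float, ...]
    bp_order: int = 6
    sample_rate: float = 22050.0
    gmap: GreenwoodMap = field(default=HUMAN_MAP)

    def band_sos(self, i: int) -> np.ndarray:
        """Second-order-section Butterworth bandpass for band ``i`` (0-based)."""
        if not 0 <= i < self.n_bands:
            raise IndexError(f"band index {i} out of range 0..{self.n_bands - 1}")
        sos = signal.butter(
            self.bp_order,
            [self.edges[i], self.edges[i + 1]],
            btype="bandpass",
            fs=self.sample_rate,
            output="sos",
        )
        # poles inside unit circle; a marginally unstable design would
        # silently corrupt every synthesis stage downstream
        z, p, _ = signal.sos2zpk(sos)
        if np.any(np.abs(p) >= 1.0):
            raise RuntimeError(f"unstable bandpass design for band {i}")
        return sos

    def to_manifest(self) -> dict:
        """JSON-serialisable reproducibility record of the bank."""
        return {
            "n_bands": self.n_bands,
            "f_lo": self.f_lo,
            "f_hi": self.f_hi,
            "edges": list(self.edges),
            "centers": list(self.centers),
            "bp_order": self.bp_order,
            "sample_rate": self.sample_rate,
            "spacing": "equal-basilar-membrane-distance",
            "greenwood": {"A": self.gmap.A, "a": self.gmap.a, "k": self.gmap.k},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_manifest(), indent=2)


def make_filterbank(
    n_bands: int,
    f_lo: float = 100.0,
    f_hi: float = 5000.0,
    sample_rate: float = 22050.0,
    bp_order: int = 6,
    gmap: GreenwoodMap = HUMAN_MAP,
) -> FilterbankSpec:
    """Build an ``n_bands``-channel filterbank with edges equally spaced in
    basilar-membrane position between ``f_lo`` and ``f_hi``.

    Raises
    ------
    ValueError
        If ``f_hi`` is at or above Nyquist, or the band count/range is invalid.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if not f_lo < f_hi:
        raise ValueError("f_lo must be below f_hi")
    if f_hi >= sample_rate / 2:
        raise ValueError(
            f"f_hi={f_hi} Hz must be below Nyquist ({sample_rate / 2} Hz)"
        )
    x_lo = greenwood_position(f_lo, gmap)
    x_hi = greenwood_position(f_hi, gmap)
    edge_pos = np.linspace(x_lo, x_hi, n_bands + 1)
    center_pos = 0.5 * (edge_pos[:-1] + edge_pos[1:])
    edges = greenwood_frequency(edge_pos, gmap)
    centers = greenwood_frequency(center_pos, gmap)
    # pin the printed endpoints exactly (linspace guarantees them anyway,
    # up to rounding in the round-trip)
    edges[0], edges[-1] = f_lo, f_hi
    return FilterbankSpec(
        n_bands=n_bands,
        f_lo=float(f_lo),
        f_hi=float(f_hi),
        edges=tuple(float(e) for e in edges),
        centers=tuple(float(c) for c in centers),
        bp_order=bp_order,
        sample_rate=float(sample_rate),
        gmap=gmap,
    )


def band_response_matrix(spec: FilterbankSpec) -> np.ndarray:
    """Magnitude response (dB) of every band evaluated at every band centre.

    Entry ``[i, j]`` is band ``i``'s gain at band ``j``'s centre frequency.
    Used to verify band selectivity of the designed digital filters.
    """
    centers = np.asarray(spec.centers)
    out = np.empty((spec.n_bands, spec.n_bands))
    for i in range(spec.n_bands):
        _, h = signal.sosfreqz(spec.band_sos(i), worN=2 * math.pi * centers / spec.sample_rate)
        out[i] = 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))
    return out
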