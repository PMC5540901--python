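"""Frequency-band definitions for resting-state BOLD decomposition.

Resting-state BOLD fluctuations are conventionally analysed either in the
broad low-frequency-oscillation (LFO) band or after decomposition into the
"slow" bands of the neurophysiological oscillation taxonomy.  With a
repetition time of 2 s the Nyquist frequency is 0.25 Hz, so slow-2 is
half-open at the top of the sampled spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency interval in Hz.

    ``low_hz < high_hz`` and both must be positive; ``high_hz`` may equal
    the Nyquist frequency of the acquisition (in which case the band is
    realized as a high-pass, see :func:`dmnfc.preprocess.bandpass_filter`).
    """

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low_hz < high_hz, "
                f"got ({self.low_hz}, {self.high_hz})"
            )

    def validate_for_tr(self, tr_seconds: float) -> None:
        """Raise ``ValueError`` if the band exceeds Nyquist for this TR."""
        nyquist = 0.5 / tr_seconds
        if self.high_hz > nyquist + 1e-12:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high_hz} Hz exceeds "
                f"Nyquist {nyquist} Hz for TR={tr_seconds} s"
            )

    @property
    def center_hz(self) -> float:
        """Geometric band centre."""
        return float((self.low_hz * self.high_hz) ** 0.5)


#: The five canonical analysis bands (Hz) at TR = 2 s.
LFO = BandSpec("lfo", 0.01, 0.08)
SLOW5 = BandSpec("slow-5", 0.01, 0.027)
SLOW4 = BandSpec("slow-4", 0.027, 0.073)
SLOW3 = BandSpec("slow-3", 0.073, 0.198)
SLOW2 = BandSpec("slow-2", 0.198, 0.25)

CANONICAL_BANDS: dict[str, BandSpec] = {
    b.name: b for b in (LFO, SLOW5, SLOW4, SLOW3, SLOW2)
}

#: The four mutually disjoint "slow" bands (no LFO, which overlaps slow-5/4).
SLOW_BANDS: dict[str, BandSpec] = {
    b.name: b for b in (SLOW5, SLOW4, SLOW3, SLOW2)
}


def get_band(name: str) -> BandSpec:
    """Look up a canonical band by name (e.g. ``"slow-4"``)."""
    try:
        return CANONICAL_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(CANONICAL_BANDS)}"
        ) from None
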