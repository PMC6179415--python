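"""Spectral detection channels of the fiber-probe spectrofluorometer.

Two pulsed diode lasers (372 nm and 438 nm, 20 MHz) excite tissue
autofluorescence, which is split into three emission bands detected by
photon-counting PMTs. The UV-excited bands are Channels 1-3; the
blue-excited long-wavelength band is Channel 4. CH2 reports mostly
NAD(P)H, CH4 mostly FAD, CH3 a mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ChannelConfig", "CHANNELS", "CHANNEL_NAMES"]


@dataclass(frozen=True)
class ChannelConfig:
    """One excitation/emission band of the instrument."""

    name: str
    excitation_nm: float
    emission_center_nm: float
    emission_halfwidth_nm: float

    @property
    def emission_band(self) -> tuple[float, float]:
        return (
            self.emission_center_nm - self.emission_halfwidth_nm,
            self.emission_center_nm + self.emission_halfwidth_nm,
        )


#: The four instrument channels (excitation nm, emission center ± halfwidth nm).
CHANNELS: dict[str, ChannelConfig] = {
    "CH1": ChannelConfig("CH1", 372.0, 410.0, 10.0),
    "CH2": ChannelConfig("CH2", 372.0, 455.0, 25.0),
    "CH3": ChannelConfig("CH3", 372.0, 525.0, 25.0),
    "CH4": ChannelConfig("CH4", 438.0, 525.0, 25.0),
}

CHANNEL_NAMES: tuple[str, ...] = tuple(CHANNELS)
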