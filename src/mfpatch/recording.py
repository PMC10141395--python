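"""The :class:`Recording` container: a current trace plus protocol metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, ParameterError

#: Test potentials used by the voltage-step protocol, in mV.
PROTOCOL_VOLTAGES_MV = (-100.0, -80.0, -60.0, 60.0, 80.0, 100.0)


@dataclass
class Recording:
    """A sampled single-channel current trace with protocol metadata.

    Parameters
    ----------
    values
        Current samples in amperes, one per sampling interval.
    dt
        Sampling interval in seconds (must be positive).
    voltage_mV
        Test potential of the voltage-step protocol, if any.
    replicate
        1-based replicate identifier within a condition.
    condition
        Free-form condition label (e.g. ``"control"``, ``"IAA"``).
    incubation_min
        Incubation time in minutes for treatment conditions, if any.
    extra
        Passthrough metadata (unknown header keys from recording files).
    """

    values: np.ndarray
    dt: float
    voltage_mV: float | None = None
    replicate: int | None = None
    condition: str | None = None
    incubation_min: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("recording values must be one-dimensional")
        if self.values.size < 2:
            raise InputError("a recording needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            idx = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise InputError(f"non-finite sample at index {idx}")
        if not (self.dt > 0):
            raise ParameterError(f"sampling interval must be positive, got {self.dt}")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Total duration in seconds (n_samples * dt)."""
        return self.n_samples * self.dt

    def times(self) -> np.ndarray:
        """Sample times in seconds; sample ``i`` (0-based) is at ``i * dt``."""
        return np.arange(self.n_samples) * self.dt

    def validate_protocol_voltage(self, voltages=PROTOCOL_VOLTAGES_MV) -> None:
        """Raise if the recording's test voltage is not in the protocol set."""
        if self.voltage_mV is None or float(self.voltage_mV) not in set(voltages):
            raise ParameterError(
                f"voltage {self.voltage_mV} mV not in protocol set {sorted(voltages)}"
            )
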