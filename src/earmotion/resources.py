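"""Resource proxies, device registry, feasibility scoring, and the
hardware-in-the-loop (HIL) measurement contract with a mock backend.

Proxies mirror how a tiny-ML runtime spends memory: flash holds the
serialized nonzero weights plus a fixed schema overhead; SRAM is dominated
by the activation arena, approximated by the largest per-layer
input+activation footprint plus an interpreter constant; FLOPS (1 MAC = 2
FLOPs) stand in for latency. Feasibility terms are normalized by the device
budget and switch to an infinite penalty when a budget is exceeded, so a
minimized composite rewards models that fill — but never overflow — the
device.

Real serial/RTOS backends are out of scope; ``MockHil`` emulates one by
adding configurable interpreter/RTOS overheads and a latency linear in
FLOPS, which is what distinguishes on-device measurements from proxies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DeviceSpec",
    "ResourceReport",
    "flash_proxy",
    "sram_proxy",
    "flops_count",
    "proxy_report",
    "feasibility",
    "MockHil",
    "HilUnavailable",
    "hil_measure",
    "STANDARD_DEVICES",
]

FLASH_OVERHEAD_BYTES = 2048  # serialized-schema constant
SRAM_OVERHEAD_BYTES = 4096  # interpreter/persistent-buffer constant
BYTES_PER_FLOAT = 4
BYTES_PER_QUANTIZED = 1


@dataclass(frozen=True)
class DeviceSpec:
    name: str
    sram_max_kb: float
    flash_max_kb: float
    target_mflops: float = 10.0
    target_latency_ms: float | None = None
    hil_available: bool = False

    def __post_init__(self) -> None:
        if self.sram_max_kb <= 0 or self.flash_max_kb <= 0:
            raise ValueError("device budgets must be positive")

    @property
    def sram_max_bytes(self) -> float:
        return self.sram_max_kb * 1024

    @property
    def flash_max_bytes(self) -> float:
        return self.flash_max_kb * 1024


# registry mirroring the microcontroller classes evaluated for the search
STANDARD_DEVICES = {
    d.name: d
    for d in [
        DeviceSpec("csr8670-earbud", sram_max_kb=128, flash_max_kb=16000),
        DeviceSpec("stm32f446re", sram_max_kb=128, flash_max_kb=512, hil_available=True),
        DeviceSpec("stm32f407vet6", sram_max_kb=192, flash_max_kb=512),
        DeviceSpec("stm32l476rg", sram_max_kb=128, flash_max_kb=1024, hil_available=True),
        DeviceSpec("stm32f746zg", sram_max_kb=320, flash_max_kb=1024, hil_available=True),
    ]
}


def load_device(path_or_name: str | Path) -> DeviceSpec:
    """Load a device from the registry by name or from a JSON file."""
    if str(path_or_name) in STANDARD_DEVICES:
        return STANDARD_DEVICES[str(path_or_name)]
    data = json.loads(Path(path_or_name).read_text())
    return DeviceSpec(**data)


@dataclass(frozen=True)
class ResourceReport:
    flash_bytes: float
    sram_bytes: float
    flops: float
    latency_ms: float | None = None
    source: str = "proxy"

    def __post_init__(self) -> None:
        if min(self.flash_bytes, self.sram_bytes, self.flops) < 0:
            raise ValueError("resource figures must be non-negative")


def flash_proxy(model) -> int:
    """Serialized model size: nonzero stored weights x bytes-per-weight plus
    a fixed schema overhead."""
    bytes_per = BYTES_PER_QUANTIZED if getattr(model, "quantized", False) else BYTES_PER_FLOAT
    nnz = sum(int(np.count_nonzero(a)) for a in model.weight_arrays().values())
    return nnz * bytes_per + FLASH_OVERHEAD_BYTES


def sram_proxy(model, input_shape) -> int:
    """Arena estimate: max over layers of (inputs + activations) elements
    times bytes-per-element, plus the interpreter constant."""
    bytes_per = BYTES_PER_QUANTIZED if getattr(model, "quantized", False) else BYTES_PER_FLOAT
    profile = model.activation_profile(input_shape)
    if not profile:
        raise ValueError("model reports no activation profile")
    peak = max(x + a for x, a in profile)
    return peak * bytes_per + SRAM_OVERHEAD_BYTES


def flops_count(model, input_shape) -> int:
    """Total FLOPs for one inference (1 multiply-accumulate = 2 FLOPs)."""
    return int(model.flops(input_shape))


def proxy_report(model, input_shape) -> ResourceReport:
    return ResourceReport(
        flash_bytes=flash_proxy(model),
        sram_bytes=sram_proxy(model, input_shape),
        flops=flops_count(model, input_shape),
        latency_ms=None,
        source="proxy",
    )


def feasibility(
    report: ResourceReport, dev: DeviceSpec
) -> tuple[float, float, float]:
    """Normalized objective terms (f_flash, f_sram, f_latency).

    Within budget, flash and SRAM terms are negative utilizations (filling
    the device is rewarded under minimization); exceeding a budget yields
    +inf. Latency is FLOPS (or HIL latency) over its target.
    """
    f_flash = (
        -report.flash_bytes / dev.flash_max_bytes
        if report.flash_bytes <= dev.flash_max_bytes
        else np.inf
    )
    f_sram = (
        -report.sram_bytes / dev.sram_max_bytes
        if report.sram_bytes <= dev.sram_max_bytes
        else np.inf
    )
    if report.latency_ms is not None and dev.target_latency_ms is not None:
        f_lat = report.latency_ms / dev.target_latency_ms
    else:
        f_lat = report.flops / (dev.target_mflops * 1e6)
    return float(f_flash), float(f_sram), float(f_lat)


class HilUnavailable(RuntimeError):
    """Raised when a HIL backend cannot serve a measurement."""


class MockHil:
    """Mock hardware-in-the-loop backend.

    Reports proxy resources plus interpreter/RTOS overheads the proxies
    cannot see, and a latency linear in FLOPS with a small measurement
    noise: latency_ms = a * FLOPS + b + N(0, noise_sd).
    """

    def __init__(
        self,
        flash_overhead_bytes: float = 0.0,
        sram_overhead_bytes: float = 0.0,
        latency_per_flop_ms: float = 1e-6,
        latency_base_ms: float = 2.0,
        latency_noise_sd_ms: float = 0.0,
        seed: int = 0,
        available: bool = True,
    ):
        self.flash_overhead_bytes = flash_overhead_bytes
        self.sram_overhead_bytes = sram_overhead_bytes
        self.latency_per_flop_ms = latency_per_flop_ms
        self.latency_base_ms = latency_base_ms
        self.latency_noise_sd_ms = latency_noise_sd_ms
        self.available = available
        self._rng = np.random.default_rng(seed)

    def measure(self, model, input_shape) -> ResourceReport:
        if not self.available:
            raise HilUnavailable("mock backend marked unavailable")
        base = proxy_report(model, input_shape)
        latency = (
            self.latency_per_flop_ms * base.flops
            + self.latency_base_ms
            + (self._rng.normal(0, self.latency_noise_sd_ms) if self.latency_noise_sd_ms else 0.0)
        )
        return ResourceReport(
            flash_bytes=base.flash_bytes + self.flash_overhead_bytes,
            sram_bytes=base.sram_bytes + self.sram_overhead_bytes,
            flops=base.flops,
            latency_ms=max(latency, 0.0),
            source="hil",
        )


def hil_measure(backend, model, input_shape) -> ResourceReport:
    """Measure through a HIL backend; raises HilUnavailable on failure so a
    caller (e.g. the architecture search) can fall back to proxies."""
    if backend is None:
        raise HilUnavailable("no backend configured")
    return backend.measure(model, input_shape)
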