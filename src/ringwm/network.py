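"""EB-PB spiking ring-attractor circuit.

The network has six populations: EIP neurons (one per EB wedge, 18 wedges
of 20 deg), PEI and PEN neurons (9 glomeruli per PB side), and three
GABAergic ring-neuron pools of 8 units each. EIP and PEI form the recurrent
C circuit that stabilizes the activity bump; EIP and PEN form the P circuit
that shifts it; EIP-ring neurons provide global inhibition setting bump
width, while C-ring and P-ring pools gate PEI and PEN respectively.

Wiring follows the reference weight table. Each PEI/PEN has a central and a
peripheral EB target (the peripheral sits 8 wedges clockwise of the
central); end-of-fan units carry the atypical connection class. PEN output
maps are offset by one wedge relative to the PEI maps, in opposite
directions on the two PB sides, which realizes clockwise bump rotation for
left-PB input and counterclockwise rotation for right-PB input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ringwm.errors import ConstructionError, IntegrationError, TopologyError
from ringwm import simcore

__all__ = [
    "LIFParams",
    "SynapseKinetics",
    "WeightTable",
    "Topology",
    "StimulationParams",
    "CalibrationParams",
    "Network",
    "DriveSchedule",
    "SpikeRecord",
    "DEFAULT_KINETICS",
    "N_WEDGES",
    "WEDGE_DEG",
    "build_network",
    "integrate",
    "apply_ring_modulation",
    "deliver_visual_input",
    "deliver_rotation_input",
    "wedge_of_azimuth",
    "wedge_center_deg",
]

N_WEDGES = 18
WEDGE_DEG = 360.0 / N_WEDGES
N_GLOM = 9  # PB glomeruli per side
RING_POOL = 8  # units per ring-neuron pool

POPULATIONS = ("eip", "pei_left", "pei_right", "pen_left", "pen_right",
               "eip_ring", "c_ring", "p_ring")

#: Aliases accepted by :func:`apply_ring_modulation`.
RING_ALIASES = {
    "eip_ring": "eip_ring",
    "eip-ring": "eip_ring",
    "ring_eip": "eip_ring",
    "c_ring": "c_ring",
    "c-ring": "c_ring",
    "p_ring": "p_ring",
    "p-ring": "p_ring",
}


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters, shared by all neurons.

    The source model's microparameters are not printed; these are standard
    cortical-style values, with the capacitance calibrated so the printed
    manipulation currents (-0.04, -0.25, +0.20 nA) reproduce the reported
    bump phenotypes against a rheobase of 0.07 nA.
    """

    tau_m_ms: float = 20.0
    v_rest_mv: float = -70.0
    v_thr_mv: float = -50.0
    v_reset_mv: float = -55.0
    refractory_ms: float = 2.0
    capacitance_nf: float = 0.07

    def __post_init__(self) -> None:
        if self.v_thr_mv <= self.v_reset_mv:
            raise ValueError("threshold must exceed reset")
        if min(self.tau_m_ms, self.refractory_ms, self.capacitance_nf) <= 0:
            raise ValueError("time constants and capacitance must be positive")

    @property
    def resistance_mohm(self) -> float:
        return self.tau_m_ms / self.capacitance_nf  # MOhm

    @property
    def rheobase_na(self) -> float:
        return (self.v_thr_mv - self.v_rest_mv) / self.resistance_mohm


@dataclass(frozen=True)
class SynapseKinetics:
    """Single-exponential conductance kinetics for one receptor type."""

    receptor: str  # "NMDA" or "GABA"
    decay_ms: float
    reversal_mv: float

    def __post_init__(self) -> None:
        if self.receptor not in ("NMDA", "GABA"):
            raise ValueError("receptor must be NMDA or GABA")
        if self.decay_ms <= 0:
            raise ValueError("decay time constant must be positive")


DEFAULT_KINETICS: Mapping[str, SynapseKinetics] = {
    "NMDA": SynapseKinetics("NMDA", 100.0, 0.0),
    "GABA": SynapseKinetics("GABA", 10.0, -70.0),
}

# (source_type, target_type, connection_class) -> dimensionless weight
REQUIRED_CELLS: dict[tuple[str, str, str], float] = {
    ("EIP", "PEI", "uniform"): 4.0,
    ("EIP", "PEN", "uniform"): 4.0,
    ("EIP", "Ring-EIP", "uniform"): 1.0,
    ("PEI", "EIP", "central"): 8.0,
    ("PEI", "EIP", "peripheral"): 4.0,
    ("PEI", "EIP", "atypical"): 4.0,
    ("PEN", "EIP", "central"): 10.0,
    ("PEN", "EIP", "peripheral"): 5.0,
    ("PEN", "EIP", "atypical"): 15.0,
    ("Ring-EIP", "EIP", "uniform"): 3.0,
    ("Ring-EIP", "Ring-EIP", "uniform"): 1.6,
    ("Ring-PEI", "PEI", "uniform"): 10.0,
    ("Ring-PEN", "PEN", "uniform"): 10.0,
}


@dataclass(frozen=True)
class WeightTable:
    """Synaptic weights between neuron types, keyed by connection class."""

    entries: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(REQUIRED_CELLS)
    )

    def __post_init__(self) -> None:
        for cell in REQUIRED_CELLS:
            if cell not in self.entries:
                raise ConstructionError(f"missing weight-table cell {cell}")
        for cell, w in self.entries.items():
            if cell not in REQUIRED_CELLS:
                raise ConstructionError(f"unknown weight-table cell {cell}")
            if w < 0:
                raise ConstructionError(f"negative weight for cell {cell}")

    def __getitem__(self, cell: tuple[str, str, str]) -> float:
        return self.entries[cell]

    def scaled(self, factor: float) -> "WeightTable":
        return WeightTable({k: v * factor for k, v in self.entries.items()})


def wedge_of_azimuth(azimuth_deg: float) -> int:
    """Wedge i covers [i*20, (i+1)*20) degrees."""
    return int(np.floor((azimuth_deg % 360.0) / WEDGE_DEG)) % N_WEDGES


def wedge_center_deg(wedge: int) -> float:
    return (wedge % N_WEDGES + 0.5) * WEDGE_DEG


@dataclass(frozen=True)
class Topology:
    """Index maps between EB wedges and PB glomeruli.

    PEI glomeruli fan over contiguous half-rings: left glomerulus j targets
    wedge (10+j) mod 18 centrally (end units j=7, 8 reach wedges 17 and 0
    through the atypical class), the right side mirrors over the remaining
    wedges; each PEI also has a peripheral target 8 wedges clockwise of its
    central one and receives input from the EIP of its central wedge.

    PEN glomeruli instead interleave: each side tiles the full ring at
    stride 2 (left even wedges from 10, right odd wedges from 11), so a
    unilateral PB input can move the bump anywhere on the ring. A PEN's
    central/peripheral targets follow the same central/-8 rule, but its
    EIP input comes from one wedge counterclockwise (left side) or
    clockwise (right side) of its central target — left-PB activity
    therefore pushes the bump clockwise and right-PB activity pushes it
    counterclockwise.
    """

    n_wedges: int = N_WEDGES
    n_glomeruli_per_side: int = N_GLOM
    shift_offset: int = 1

    def pei_map(self, side: str, j: int) -> dict[str, int | str]:
        """Input wedge, central/peripheral targets and class of one PEI.

        The two end units of each side are atypical: each targets BOTH end
        wedges of its fan (e.g., PEI7 and PEI8 each reach EIP0 and EIP17),
        so those wedges receive the same summed central weight as the rest
        of the ring.
        """
        c = (10 + j) % self.n_wedges if side == "left" else (1 + j) % self.n_wedges
        cls = "atypical" if j >= self.n_glomeruli_per_side - 2 else "central"
        peri = (c - 8) % self.n_wedges
        out = {
            "input": c,
            "central": c,
            "peripheral": peri,
            "class": cls,
        }
        if cls == "atypical":
            ends = (
                ((10 + 7) % self.n_wedges, (10 + 8) % self.n_wedges)
                if side == "left"
                else ((1 + 7) % self.n_wedges, (1 + 8) % self.n_wedges)
            )
            out["atypical_pair"] = ends
        return out

    def pen_map(self, side: str, j: int) -> dict[str, int | str]:
        if side == "left":
            c = (10 + 2 * j) % self.n_wedges
            inp = (c + self.shift_offset) % self.n_wedges
            peri = (c - 8) % self.n_wedges
        else:
            c = (11 - 2 * j) % self.n_wedges
            inp = (c - self.shift_offset) % self.n_wedges
            peri = (c + 8) % self.n_wedges
        cls = "atypical" if j >= self.n_glomeruli_per_side - 2 else "central"
        return {
            "input": inp,
            "central": c,
            "peripheral": peri,
            "class": cls,
        }

    def validate(self) -> None:
        """Check the structural anchors; raise :class:`TopologyError` if broken."""
        pei0 = self.pei_map("left", 0)
        if pei0["central"] != 10 or pei0["peripheral"] != 2:
            raise TopologyError("left PEI0 must target EIP10 (central) and EIP2 (peripheral)")
        ends = {self.pei_map("left", 7)["central"], self.pei_map("left", 8)["central"]}
        if ends != {17, 0}:
            raise TopologyError("atypical PEI7/PEI8 must reach EIP0/EIP17")
        pen0 = self.pen_map("left", 0)
        if pen0["central"] != 10 or pen0["peripheral"] != 2:
            raise TopologyError("PEN0 must target EIP10 (central) and EIP2 (peripheral)")
        # central coverage of the full ring by each bilateral population,
        # and per-side full-ring PEN coverage (needed for unilateral shifts)
        for mapper in (self.pei_map, self.pen_map):
            covered = {
                mapper(side, j)["central"]
                for side in ("left", "right")
                for j in range(self.n_glomeruli_per_side)
            }
            if len(covered) < self.n_wedges:
                raise TopologyError("central targets leave the ring under-covered")
        for side in ("left", "right"):
            span = max(
                abs((self.pen_map(side, j)["central"] - self.pen_map(side, j2)["central"]))
                for j in range(self.n_glomeruli_per_side)
                for j2 in range(self.n_glomeruli_per_side)
            )
            if span < self.n_wedges - 3:
                raise TopologyError(f"{side} PEN glomeruli do not span the ring")
        loff = (self.pen_map("left", 0)["input"] - self.pen_map("left", 0)["central"]) % self.n_wedges
        roff = (self.pen_map("right", 0)["input"] - self.pen_map("right", 0)["central"]) % self.n_wedges
        if loff == roff:
            raise TopologyError("PEN side offsets must point in opposite directions")


@dataclass(frozen=True)
class StimulationParams:
    """Protocol currents (nA) and input spike rates (Hz)."""

    eip_ring_suppression_na: float = -0.04
    p_ring_suppression_na: float = -0.25
    photoactivation_na: float = 0.20
    gate_current_na: float = 0.14
    #: fraction of the gate current applied to the P-ring pool during
    #: rotation states: the P circuit is only partially released, so the
    #: side receiving rotation input dominates the bump shift.
    rotation_gate_fraction: float = 0.38
    #: fraction of the gate current applied to the C-ring pool during
    #: rotation states; slightly below 1 leaves residual C-circuit support
    #: so brief rotations cannot extinguish the bump.
    c_gate_fraction: float = 0.9
    visual_input_rate_hz: float = 400.0
    rotation_input_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.eip_ring_suppression_na >= 0 or self.p_ring_suppression_na >= 0:
            raise ValueError("suppression currents must be negative")
        if self.photoactivation_na <= 0:
            raise ValueError("photoactivation current must be positive")


@dataclass(frozen=True)
class CalibrationParams:
    """Free scale parameters tuned so the wild-type bump has FWHM ~ 1.86 rad.

    Conductance units are maximum conductances: NMDA synapses saturate via
    their gating variable (jump ``nmda_alpha * (1 - s)`` per spike), so a
    weight-w synapse contributes at most ``w * g_exc_unit_us``.
    """

    g_exc_unit_us: float = 9.3e-4  # max NMDA conductance per weight unit
    g_inh_unit_us: float = 1.4e-3  # GABA conductance jump per weight unit
    nmda_alpha: float = 0.63
    background_rate_hz: float = 150.0
    background_amp_us: float = 4.7e-4  # conductance jump of the background channel
    background_tau_ms: float = 5.0  # fast decay: the background is the noise source
    ring_background_scale: float = 1.0  # ring pools get scaled-down background noise
    #: linear spread of standing currents across each ring pool's units;
    #: makes the pool's input-output curve graded instead of all-or-none.
    ring_bias_spread_na: float = 0.047
    #: upward bias spread of the EIP-ring pool; sets how gradually the pool
    #: drops out under the suppression current (width sensitivity).
    eip_ring_bias_spread_na: float = 0.10
    visual_amp_us: float = 2.8e-3  # max conductance of the visual-input gate (PEI)
    #: scale of the direct EB (EIP) share of the cue stream, relative to
    #: visual_amp_us; keeps the cued wedge excitable under photoactivation
    #: without over-pinning the stimulus-stage bump.
    eip_visual_scale: float = 0.3
    rotation_amp_us: float = 1.4e-3  # max conductance of the rotation-input gate (PEN)
    visual_spread_wedges: int = 1
    #: Gaussian arborization width (in wedges) of PB->EB terminals; each
    #: connection's weight is distributed over neighboring wedges with this
    #: spread, and the emergent bump width grows with it.
    arbor_sigma_wedges: float = 2.5
    arbor_reach_wedges: int = 5
    #: width of the EB->PB (dendritic) sampling kernel; kept narrower than
    #: the output arbor so the one-wedge PEN offset stays directional.
    input_sigma_wedges: float = 0.7
    #: tonic depolarization of the EIP-ring pool (the pool is active
    #: throughout); sets the operating point that the printed
    #: suppression/photoactivation currents act against.
    eip_ring_bias_na: float = -0.21
    #: scale of EIP->Ring-EIP synaptic drive.
    ring_input_scale: float = 1.0
    #: scale of the all-to-all Ring-EIP pool self-inhibition; sets how hard
    #: the pool can escalate before damping itself (the escalation ceiling
    #: must sit below the P-circuit overdrive for suppression to spread it).
    ring_self_scale: float = 0.8
    #: standing hyperpolarization of PEN units (0 = none).
    pen_bias_na: float = 0.0
    #: spike-frequency adaptation of EIP/PEI/PEN units: conductance jump per
    #: own spike and its decay; flattens the bump top (widens FWHM).
    adapt_inc_us: float = 1.0e-4
    adapt_tau_ms: float = 200.0
    #: slow adaptation of the P-ring pool: driven hard for tens of seconds
    #: (photoactivation) it under-gates for a few seconds afterwards,
    #: transiently over-activating the P circuit.
    ring_adapt_inc_us: float = 0.0
    ring_adapt_tau_ms: float = 2000.0


@dataclass
class Network:
    """Instantiated circuit: population layout, neuron params, synapse lists."""

    lif: LIFParams
    kinetics: Mapping[str, SynapseKinetics]
    weight_table: WeightTable
    topology: Topology
    calibration: CalibrationParams
    seed: int
    pop_slices: dict[str, slice]
    exc_ptr: np.ndarray
    exc_tgt: np.ndarray
    exc_g: np.ndarray
    inh_ptr: np.ndarray
    inh_tgt: np.ndarray
    inh_g: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.pop_slices["p_ring"].stop

    def population_of(self, idx: np.ndarray | int) -> np.ndarray:
        names = np.empty(self.n_neurons, dtype=object)
        for name, sl in self.pop_slices.items():
            names[sl] = name
        return names[idx]

    def indices(self, population: str) -> np.ndarray:
        return np.arange(*self.pop_slices[population].indices(self.n_neurons))

    def eip_index(self, wedge: int) -> int:
        return self.pop_slices["eip"].start + (wedge % N_WEDGES)

    def synapse_weight(self, src: int, tgt: int) -> float | None:
        """Summed max conductance (uS) of synapses src->tgt, or None if absent."""
        total = 0.0
        found = False
        for ptr, tgts, gs in (
            (self.exc_ptr, self.exc_tgt, self.exc_g),
            (self.inh_ptr, self.inh_tgt, self.inh_g),
        ):
            for k in range(ptr[src], ptr[src + 1]):
                if tgts[k] == tgt:
                    total += float(gs[k])
                    found = True
        return total if found else None

    def dimensionless_weight(self, src: int, tgt: int) -> float | None:
        """Summed table weight of synapses src->tgt (conductance / unit scale)."""
        g = self.synapse_weight(src, tgt)
        if g is None:
            return None
        gaba = any(
            self.inh_tgt[k] == tgt for k in range(self.inh_ptr[src], self.inh_ptr[src + 1])
        )
        unit = self.calibration.g_inh_unit_us if gaba else self.calibration.g_exc_unit_us
        return g / unit


@dataclass
class SpikeRecord:
    """Spike times (ms) and neuron ids for one integration run."""

    times_ms: np.ndarray
    neuron_ids: np.ndarray
    duration_ms: float
    dt_ms: float
    v_final: np.ndarray
    network: Network

    def to_frame(self):
        """Columnar spike table: neuron_id, population, time_ms."""
        import pandas as pd

        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "population": self.network.population_of(self.neuron_ids)
                if len(self.neuron_ids)
                else np.array([], dtype=object),
                "time_ms": self.times_ms,
            }
        )

    def spikes_of(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        sl = self.network.pop_slices[population]
        m = (self.neuron_ids >= sl.start) & (self.neuron_ids < sl.stop)
        return self.times_ms[m], self.neuron_ids[m] - sl.start

    def rate_of(self, population: str, window_ms: tuple[float, float] | None = None) -> float:
        """Mean per-neuron firing rate (Hz) of a population."""
        t, _ = self.spikes_of(population)
        lo, hi = window_ms if window_ms else (0.0, self.duration_ms)
        n_units = self.network.pop_slices[population].stop - self.network.pop_slices[population].start
        n_spk = int(np.count_nonzero((t >= lo) & (t < hi)))
        return 1e3 * n_spk / ((hi - lo) * n_units)


class DriveSchedule:
    """Piecewise-constant per-neuron drives over fixed blocks.

    Holds injected current (nA) plus two Poisson conductance channels:
    channel 'a' for background drive, channel 'b' for visual/rotation input.
    """

    def __init__(self, network: Network, duration_ms: float, block_ms: float = 300.0):
        n_blocks = max(1, int(np.ceil(duration_ms / block_ms - 1e-9)))
        self.network = network
        self.duration_ms = float(duration_ms)
        self.block_ms = float(block_ms)
        self.n_blocks = n_blocks
        n = network.n_neurons
        self.i_ext = np.zeros((n_blocks, n))
        self.rate_a = np.zeros((n_blocks, n))
        self.rate_b = np.zeros((n_blocks, n))
        cal = network.calibration
        # channel a: background gate; channel b: visual (PEI/EIP) / rotation (PEN)
        self.amp_a = np.full(n, cal.background_amp_us)
        self.amp_b = np.full(n, cal.visual_amp_us)
        self.amp_b[network.pop_slices["eip"]] = cal.visual_amp_us * cal.eip_visual_scale
        for side in ("left", "right"):
            self.amp_b[network.pop_slices[f"pen_{side}"]] = cal.rotation_amp_us

    def _block_range(self, window_ms: tuple[float, float]) -> tuple[int, int]:
        t0, t1 = window_ms
        if t0 < -1e-9 or t1 > self.duration_ms + 1e-9 or t1 < t0:
            raise ValueError(f"window {window_ms} outside trial [0, {self.duration_ms}] ms")
        b0 = int(np.floor(t0 / self.block_ms + 1e-9))
        b1 = int(np.ceil(t1 / self.block_ms - 1e-9))
        return max(0, b0), min(self.n_blocks, b1)

    def add_current(self, neuron_idx, current_na: float, window_ms: tuple[float, float]) -> None:
        b0, b1 = self._block_range(window_ms)
        self.i_ext[b0:b1, neuron_idx] += current_na

    def add_poisson(
        self, channel: str, neuron_idx, rate_hz: float, window_ms: tuple[float, float]
    ) -> None:
        if rate_hz < 0:
            raise ValueError("Poisson rate must be non-negative")
        b0, b1 = self._block_range(window_ms)
        table = self.rate_a if channel == "a" else self.rate_b
        table[b0:b1, neuron_idx] += rate_hz

    def add_background(self, rate_hz: float | None = None) -> None:
        """Background Poisson drive to all EIP/PEI/PEN units plus the EIP-ring bias."""
        net = self.network
        rate = net.calibration.background_rate_hz if rate_hz is None else rate_hz
        # PEN units get no background: with it, rotation input alone could
        # re-seed a bump after the attractor has been extinguished
        idx = np.concatenate(
            [net.indices(p) for p in net.pop_slices if p not in ("pen_left", "pen_right")]
        )
        self.rate_a[:, idx] += rate
        spread = net.calibration.ring_bias_spread_na
        for ring in ("eip_ring", "c_ring", "p_ring"):
            sl = net.pop_slices[ring]
            self.amp_a[sl] = (
                net.calibration.background_amp_us * net.calibration.ring_background_scale
            )
            n_units = sl.stop - sl.start
            if ring == "eip_ring":
                # upward spread: the suppression current silences only the
                # least-driven units, so the bump widens gradually
                self.i_ext[:, sl] += np.linspace(
                    0.0, net.calibration.eip_ring_bias_spread_na, n_units
                )
            else:  # graded gate response of the C/P gating pools
                self.i_ext[:, sl] += np.linspace(-spread, 0.0, n_units)
        self.i_ext[:, net.pop_slices["eip_ring"]] += net.calibration.eip_ring_bias_na
        for side in ("left", "right"):
            self.i_ext[:, net.pop_slices[f"pen_{side}"]] += net.calibration.pen_bias_na


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_network(
    weight_table: WeightTable | None = None,
    topology: Topology | None = None,
    lif: LIFParams | None = None,
    kinetics: Mapping[str, SynapseKinetics] | None = None,
    calibration: CalibrationParams | None = None,
    seed: int = 0,
) -> Network:
    """Instantiate the circuit from the weight table and topology.

    Raises :class:`ConstructionError` for missing weight cells and
    :class:`TopologyError` for anchor violations. Deterministic given seed.
    """
    wt = weight_table if weight_table is not None else WeightTable()
    topo = topology if topology is not None else Topology()
    topo.validate()
    lif = lif or LIFParams()
    kin = dict(kinetics or DEFAULT_KINETICS)
    cal = calibration or CalibrationParams()

    sizes = {
        "eip": N_WEDGES,
        "pei_left": N_GLOM,
        "pei_right": N_GLOM,
        "pen_left": N_GLOM,
        "pen_right": N_GLOM,
        "eip_ring": RING_POOL,
        "c_ring": RING_POOL,
        "p_ring": RING_POOL,
    }
    slices: dict[str, slice] = {}
    start = 0
    for name in POPULATIONS:
        slices[name] = slice(start, start + sizes[name])
        start += sizes[name]
    n = start

    ge, gi = cal.g_exc_unit_us, cal.g_inh_unit_us
    pre_exc: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    pre_inh: list[list[tuple[int, float]]] = [[] for _ in range(n)]

    def connect(src: int, tgt: int, weight: float, gaba: bool) -> None:
        if gaba:
            g = weight * gi
            if g > 0:
                pre_inh[src].append((tgt, g))
        else:
            g = weight * ge
            if g > 0:
                pre_exc[src].append((tgt, g))

    eip0 = slices["eip"].start

    reach = cal.arbor_reach_wedges
    offsets = np.arange(-reach, reach + 1)
    kern = np.exp(-0.5 * (offsets / max(cal.arbor_sigma_wedges, 1e-6)) ** 2)
    kern /= kern.sum()
    kern_in = np.exp(-0.5 * (offsets / max(cal.input_sigma_wedges, 1e-6)) ** 2)
    kern_in /= kern_in.sum()

    def connect_eb(src: int, wedge: int, weight: float) -> None:
        """PB->EB synapse whose Gaussian arbor spans neighboring wedges."""
        for off, frac in zip(offsets, kern):
            connect(src, eip0 + (wedge + off) % N_WEDGES, weight * frac, False)

    def connect_pb(wedge: int, tgt: int, weight: float) -> None:
        """EB->PB synapse: narrower dendritic arbor over neighboring wedges."""
        for off, frac in zip(offsets, kern_in):
            connect(eip0 + (wedge + off) % N_WEDGES, tgt, weight * frac, False)

    for side in ("left", "right"):
        pei_sl = slices[f"pei_{side}"]
        pen_sl = slices[f"pen_{side}"]
        for j in range(N_GLOM):
            pm = topo.pei_map(side, j)
            pei = pei_sl.start + j
            connect_pb(pm["input"], pei, wt[("EIP", "PEI", "uniform")])
            if pm["class"] == "atypical":
                for wedge in pm["atypical_pair"]:
                    connect_eb(pei, wedge, wt[("PEI", "EIP", "atypical")])
            else:
                connect_eb(pei, pm["central"], wt[("PEI", "EIP", "central")])
            # the peripheral arbor is split into two symmetric half-weight
            # lobes; a one-sided lobe drags the bump toward it
            w_peri = wt[("PEI", "EIP", "peripheral")] / 2.0
            connect_eb(pei, (pm["central"] - 8) % N_WEDGES, w_peri)
            connect_eb(pei, (pm["central"] + 8) % N_WEDGES, w_peri)
            nm = topo.pen_map(side, j)
            pen = pen_sl.start + j
            connect_pb(nm["input"], pen, wt[("EIP", "PEN", "uniform")])
            connect_eb(pen, nm["central"], wt[("PEN", "EIP", nm["class"])])
            # PEN peripherals stay single and mirrored by side (left -8,
            # right +8): the side-specific ghost lobe is part of what pulls
            # the bump in that side's rotation direction
            connect_eb(pen, nm["peripheral"], wt[("PEN", "EIP", "peripheral")])

    for w in range(N_WEDGES):
        for r in range(*slices["eip_ring"].indices(n)):
            connect(eip0 + w, r, wt[("EIP", "Ring-EIP", "uniform")] * cal.ring_input_scale, False)
            connect(r, eip0 + w, wt[("Ring-EIP", "EIP", "uniform")], True)
    for r1 in range(*slices["eip_ring"].indices(n)):
        for r2 in range(*slices["eip_ring"].indices(n)):
            connect(
                r1, r2, wt[("Ring-EIP", "Ring-EIP", "uniform")] * cal.ring_self_scale, True
            )
    for r in range(*slices["c_ring"].indices(n)):
        for side in ("left", "right"):
            for pei in range(*slices[f"pei_{side}"].indices(n)):
                connect(r, pei, wt[("Ring-PEI", "PEI", "uniform")], True)
    for r in range(*slices["p_ring"].indices(n)):
        for side in ("left", "right"):
            for pen in range(*slices[f"pen_{side}"].indices(n)):
                connect(r, pen, wt[("Ring-PEN", "PEN", "uniform")], True)

    def to_csr(pre: list[list[tuple[int, float]]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ptr = np.zeros(n + 1, dtype=np.int64)
        ptr[1:] = np.cumsum([len(p) for p in pre])
        tgt = np.zeros(ptr[-1], dtype=np.int64)
        g = np.zeros(ptr[-1])
        k = 0
        for src in range(n):
            for t, gv in pre[src]:
                tgt[k] = t
                g[k] = gv
                k += 1
        return ptr, tgt, g

    exc_ptr, exc_tgt, exc_g = to_csr(pre_exc)
    inh_ptr, inh_tgt, inh_g = to_csr(pre_inh)
    return Network(
        lif, kin, wt, topo, cal, seed, slices, exc_ptr, exc_tgt, exc_g, inh_ptr, inh_tgt, inh_g
    )


# ---------------------------------------------------------------------------
# drive operations
# ---------------------------------------------------------------------------

def apply_ring_modulation(
    network: Network,
    drives: DriveSchedule,
    population: str,
    current_na: float,
    window_ms: tuple[float, float],
) -> DriveSchedule:
    """Add a constant current to every neuron of a ring population in a window."""
    key = RING_ALIASES.get(population.lower())
    if key is None:
        raise ValueError(f"unknown ring population {population!r}")
    if current_na != 0.0:
        drives.add_current(network.indices(key), current_na, window_ms)
    return drives


def visual_target_indices(network: Network, azimuth_deg: float) -> np.ndarray:
    """Cue-wedge units (EIP plus the PEI/PEN of the matching glomeruli).

    All three routes receive the landmark stream: during forward movement
    the gated PENs ignore it and PEI carries the cue; during rotation PEI
    is gated and the PEN route takes over; the direct EB component keeps
    the wedge excitable even under strong ring inhibition.
    """
    w = wedge_of_azimuth(azimuth_deg)
    spread = network.calibration.visual_spread_wedges
    wanted = {(w + d) % N_WEDGES for d in range(-spread, spread + 1)}
    idx = [network.eip_index(wedge) for wedge in wanted]
    for side in ("left", "right"):
        for pop, mapper in (("pei", network.topology.pei_map), ("pen", network.topology.pen_map)):
            sl = network.pop_slices[f"{pop}_{side}"]
            for j in range(N_GLOM):
                if mapper(side, j)["central"] in wanted:
                    idx.append(sl.start + j)
    return np.asarray(sorted(idx), dtype=np.int64)


def deliver_visual_input(
    network: Network,
    drives: DriveSchedule,
    landmark_azimuth_deg: float,
    rate_hz: float,
    window_ms: tuple[float, float],
) -> DriveSchedule:
    """Poisson spike input to the PB units mapped to the cued EB wedge."""
    if rate_hz < 0:
        raise ValueError("visual input rate must be non-negative")
    if not 0.0 <= landmark_azimuth_deg % 360.0 < 360.0:  # pragma: no cover - always true
        raise ValueError("azimuth must be finite")
    idx = visual_target_indices(network, landmark_azimuth_deg)
    drives.add_poisson("b", idx, rate_hz, window_ms)
    return drives


def deliver_rotation_input(
    network: Network,
    drives: DriveSchedule,
    side: str,
    rate_hz: float,
    window_ms: tuple[float, float],
) -> DriveSchedule:
    """Unilateral PB input: left induces clockwise bump rotation, right counterclockwise."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if rate_hz < 0:
        raise ValueError("rotation input rate must be non-negative")
    idx = network.indices(f"pen_{side}")
    drives.add_poisson("b", idx, rate_hz, window_ms)
    return drives


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _adapt_arrays(network: Network, dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron adaptation jump and per-step decay.

    EIP/PEI/PEN units adapt fast (bump-shape control); ring pools adapt
    slowly and weakly (post-photoactivation under-gating).
    """
    cal = network.calibration
    inc = np.zeros(network.n_neurons)
    decay = np.full(network.n_neurons, np.exp(-dt_ms / cal.adapt_tau_ms))
    for p in ("eip", "pei_left", "pei_right", "pen_left", "pen_right"):
        inc[network.pop_slices[p]] = cal.adapt_inc_us
    inc[network.pop_slices["p_ring"]] = cal.ring_adapt_inc_us
    decay[network.pop_slices["p_ring"]] = np.exp(-dt_ms / cal.ring_adapt_tau_ms)
    return inc, decay

def integrate(
    network: Network,
    duration_ms: float,
    dt_ms: float,
    drives: DriveSchedule | None = None,
    seed: int | None = None,
    spike_capacity: int | None = None,
) -> SpikeRecord:
    """Integrate the network and return its spike record.

    Fixed-step exponential Euler; Poisson drive events and spike
    propagation are resolved at dt resolution. Raises
    :class:`IntegrationError` (with time and neuron) on non-finite membrane
    potential.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if dt_ms > network.lif.refractory_ms + 1e-12:
        raise ValueError("dt must not exceed the refractory period")
    n_steps = int(round(duration_ms / dt_ms))
    if abs(n_steps * dt_ms - duration_ms) > 1e-6:
        raise ValueError("duration must be a multiple of dt")
    if drives is None:
        drives = DriveSchedule(network, duration_ms)
    steps_per_block = max(1, int(round(drives.block_ms / dt_ms)))
    if spike_capacity is None:
        spike_capacity = int(4e6)
    kin_e = network.kinetics["NMDA"]
    kin_i = network.kinetics["GABA"]
    lif = network.lif
    cal = network.calibration
    spk_t, spk_id, err, err_t, err_n, v_final = simcore.run_lif(
        network.seed if seed is None else seed,
        n_steps,
        float(dt_ms),
        steps_per_block,
        lif.tau_m_ms,
        lif.v_rest_mv,
        lif.v_thr_mv,
        lif.v_reset_mv,
        int(round(lif.refractory_ms / dt_ms)),
        lif.capacitance_nf,
        network.exc_ptr,
        network.exc_tgt,
        network.exc_g,
        network.inh_ptr,
        network.inh_tgt,
        network.inh_g,
        kin_e.decay_ms,
        kin_i.decay_ms,
        kin_e.reversal_mv,
        kin_i.reversal_mv,
        cal.nmda_alpha,
        *_adapt_arrays(network, dt_ms),
        drives.i_ext,
        drives.rate_a,
        drives.amp_a,
        cal.background_tau_ms,
        drives.rate_b,
        drives.amp_b,
        spike_capacity,
    )
    if err == simcore.ERR_NONFINITE:
        raise IntegrationError(
            f"non-finite membrane potential at t={err_t:.2f} ms, neuron {err_n}",
            time_ms=err_t,
            neuron=err_n,
        )
    if err == simcore.ERR_OVERFLOW:
        raise IntegrationError(
            f"spike record overflow at t={err_t:.2f} ms", time_ms=err_t, neuron=err_n
        )
    return SpikeRecord(spk_t.copy(), spk_id.copy(), duration_ms, dt_ms, v_final, network)
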