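"""Lattice state model for supercoiling-coupled transcription.

The DNA is a linear 1-D lattice of 60-bp segments.  Torsional state is
tracked as an integer number of linking-number units per segment, where one
unit is 0.1 helical turn: a relaxed 60-bp segment carries 60/10.5 = 5.7
turns, i.e. ``lk0_units = 57``.  Supercoiling density of a segment is

    sigma = (turn - lk0) / lk0

so a segment initialised at 54 units is at sigma = -0.0526, the homeostatic
negatively supercoiled state of the *E. coli* chromosome.

Each segment is either free or occupied by exactly one of: an elongating
RNA polymerase, a bound topoisomerase I or gyrase, or a domain-barrier
anchor.  Occupancy gates the diffusion of supercoils and the movement of
RNAP, which is what makes the lattice spatial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "FREE",
    "RNAP",
    "TOPO_I",
    "GYRASE",
    "BARRIER",
    "LatticeConfig",
    "GeneSpec",
    "TopoSpec",
    "BarrierSpec",
    "MechanicsParams",
    "SimulationConfig",
    "RNAPState",
    "LatticeState",
    "Trajectory",
    "ConfigurationError",
    "build_state",
    "sigma_of",
    "region_sigma",
    "BP_PER_NM",
]

# occupancy codes
FREE = 0
RNAP = 1
TOPO_I = 2
GYRASE = 3
BARRIER = 4

OCC_NAMES = {FREE: "free", RNAP: "rnap", TOPO_I: "topo_i", GYRASE: "gyrase", BARRIER: "barrier"}

#: B-form DNA rise, nm per base pair (used to convert segment length to a
#: physical hop distance for the diffusion coefficient).
BP_PER_NM = 0.34


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def sigma_of(turn_units: float, lk0_units: int) -> float:
    """Supercoiling density of a segment: ``(turn - lk0) / lk0``.

    Parameters
    ----------
    turn_units : number of linking-number units currently on the segment.
    lk0_units : units carried by the same segment when torsionally relaxed.

    Examples
    --------
    >>> round(sigma_of(54, 57), 4)
    -0.0526
    """
    if lk0_units <= 0:
        raise ValueError("lk0_units must be positive")
    return (turn_units - lk0_units) / lk0_units


@dataclass
class LatticeConfig:
    """Geometry and supercoil-transport parameters of the DNA lattice.

    Exactly one of ``diffusion_coefficient`` (um^2/s) and ``k_drift`` (per
    second, per-direction hop rate) must be given; the other is derived via
    ``k_drift = D / dx^2`` with ``dx = segment_bp * 0.34 nm``.

    ``boundary_mode`` per end is ``"relaxing"`` (the terminal segment is
    stochastically reset to ``boundary_target_units`` at
    ``boundary_reset_rate``, modelling torsional exchange with the rest of
    the chromosome) or ``"barrier"`` (closed end).
    """

    n_segments: int
    segment_bp: int = 60
    lk0_units: int = 57
    initial_turn_units: int = 54
    boundary_left: str = "relaxing"
    boundary_right: str = "relaxing"
    boundary_reset_rate: float = 50.0
    boundary_target_units: int = 53
    diffusion_coefficient: Optional[float] = None
    k_drift: Optional[float] = None
    diffusion_mode: str = "biased"

    def __post_init__(self) -> None:
        if self.n_segments < 3:
            raise ConfigurationError("n_segments must be >= 3")
        if self.initial_turn_units < 0:
            raise ConfigurationError("initial_turn_units must be >= 0")
        for mode in (self.boundary_left, self.boundary_right):
            if mode not in ("relaxing", "barrier"):
                raise ConfigurationError(f"unknown boundary mode {mode!r}")
        if self.diffusion_mode not in ("biased", "explicit_random_walk"):
            raise ConfigurationError(f"unknown diffusion_mode {self.diffusion_mode!r}")
        if (self.diffusion_coefficient is None) == (self.k_drift is None):
            raise ConfigurationError(
                "exactly one of diffusion_coefficient and k_drift must be given"
            )
        dx_um = self.segment_bp * BP_PER_NM * 1e-3
        if self.k_drift is None:
            self.k_drift = self.diffusion_coefficient / dx_um**2
        else:
            self.diffusion_coefficient = self.k_drift * dx_um**2

    @property
    def length_bp(self) -> int:
        return self.n_segments * self.segment_bp

    @property
    def sigma_initial(self) -> float:
        return sigma_of(self.initial_turn_units, self.lk0_units)


@dataclass
class GeneSpec:
    """A transcription unit with a supercoiling-sensitive promoter.

    The initiation rate responds piecewise-linearly to promoter
    supercoiling, between ``k_min`` (relaxed or positive sigma) and
    ``k_max`` (sigma at or below the critical density ``sigma_star``).
    ``k_elong`` is the processive translocation speed; an RNAP transcribes
    one 60-bp segment per second at the default 60 bp/s.

    ``report_window_bp`` restricts elongation-rate scoring to the first N
    transcribed bp (e.g. scoring only a lacZ-sized prefix of a longer
    operon-like unit).  ``promoter_block_after_bp`` permanently silences the
    promoter (and converts the TSS segment into a topological barrier) once
    the gene has cumulatively transcribed that many bp — the promoter-off
    experiment.
    """

    name: str
    strand: str
    tss_segment: int
    end_segment: int
    k_max: float
    k_min: float = 0.001
    sigma_star: float = -0.06
    k_elong: float = 60.0
    promoter_block_after_bp: Optional[int] = None
    mrna_decay_rate: float = 0.003
    report_window_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ConfigurationError(f"strand must be forward/reverse, got {self.strand!r}")
        if self.tss_segment == self.end_segment:
            raise ConfigurationError("tss_segment must differ from end_segment")
        if self.direction * (self.end_segment - self.tss_segment) < 0:
            raise ConfigurationError(
                f"gene {self.name}: end_segment is upstream of tss_segment for {self.strand} strand"
            )
        if self.k_min > self.k_max:
            raise ConfigurationError("k_min must be <= k_max")
        if self.sigma_star >= 0:
            raise ConfigurationError("sigma_star must be negative")

    @property
    def direction(self) -> int:
        """+1 for forward (downstream = increasing index), -1 for reverse."""
        return 1 if self.strand == "forward" else -1

    @property
    def n_segments(self) -> int:
        return abs(self.end_segment - self.tss_segment) + 1

    def length_bp(self, segment_bp: int = 60) -> int:
        return self.n_segments * segment_bp

    @property
    def span(self) -> range:
        lo = min(self.tss_segment, self.end_segment)
        return range(lo, lo + self.n_segments)


@dataclass
class TopoSpec:
    """Binding/catalysis kinetics of one topoisomerase species.

    Binding is pseudo-first-order per free segment (``k_bind``).  A bound
    enzyme occupies its segment (blocking supercoil drift into it and RNAP
    passage) until it unbinds (``k_unbind``).  Catalysis changes the
    segment's linking number by ``catalytic_step_units`` per event: +1 for
    topoisomerase I (removes one negative 0.1-turn unit, active only at
    sigma < 0) and -2 for gyrase (converts one positive supercoil to one
    negative, active only at sigma > 0).  The catalytic rate follows a
    saturating-linear response ``kcat_max * min(|sigma|/sigma_half, 1)`` on
    the active sign.
    """

    enzyme: str
    k_bind: float = 0.0018
    k_unbind: float = 1.0
    catalytic_step_units: Optional[int] = None
    kcat_max: float = 600.0
    sigma_half: float = 0.05

    def __post_init__(self) -> None:
        if self.enzyme not in ("topo_i", "gyrase"):
            raise ConfigurationError(f"enzyme must be topo_i/gyrase, got {self.enzyme!r}")
        if self.catalytic_step_units is None:
            self.catalytic_step_units = 1 if self.enzyme == "topo_i" else -2
        if self.enzyme == "topo_i" and self.catalytic_step_units <= 0:
            raise ConfigurationError("topo_i catalytic step must be positive")
        if self.enzyme == "gyrase" and self.catalytic_step_units >= 0:
            raise ConfigurationError("gyrase catalytic step must be negative")
        for r in (self.k_bind, self.k_unbind, self.kcat_max, self.sigma_half):
            if r < 0:
                raise ConfigurationError("topoisomerase rates must be >= 0")

    @property
    def active_sign(self) -> int:
        """-1: relaxes negative supercoils (topo I); +1: acts on positive (gyrase)."""
        return -1 if self.enzyme == "topo_i" else 1

    @property
    def occupancy_code(self) -> int:
        return TOPO_I if self.enzyme == "topo_i" else GYRASE


@dataclass
class BarrierSpec:
    """A pair of anchor sites whose simultaneous occupation loops the domain.

    Looping (rate ``k_loop``) atomically occupies both sites, blocking
    supercoil diffusion across them and trapping torsional stress in the
    intervening DNA; unlooping (``k_unloop``) frees both.  A ``permanent``
    barrier is always looped (control condition).
    """

    site_a: int
    site_b: int
    k_loop: float = 0.017
    k_unloop: float = 0.003
    initially_looped: bool = True
    permanent: bool = False

    def __post_init__(self) -> None:
        if self.site_a >= self.site_b:
            raise ConfigurationError("barrier requires site_a < site_b")
        if self.k_loop < 0 or self.k_unloop < 0:
            raise ConfigurationError("loop rates must be >= 0")

    @property
    def looped_fraction_stationary(self) -> float:
        """Two-state CTMC stationary looped probability k_loop/(k_loop+k_unloop)."""
        if self.permanent:
            return 1.0
        return self.k_loop / (self.k_loop + self.k_unloop)


def _coexistence_torque(cs: float, p: float, g: float, omega0: float) -> float:
    # tau0 = sqrt(2 p g / (1 - p/cs)) / omega0 : torque in the
    # twist/plectoneme coexistence region
    return float(np.sqrt(2.0 * p * g / (1.0 - p / cs)) / omega0)


@dataclass
class MechanicsParams:
    """DNA torque response and RNAP stall criteria.

    The torque carried by DNA at supercoiling density sigma follows a
    three-branch response: linear twist regime (slope ``cs * omega0``) up to
    ``sigma_s``, a constant coexistence torque while twist converts to
    plectonemic writhe, and a linear plectonemic regime (slope
    ``p * omega0``) beyond ``sigma_p``.  ``cs`` and ``p`` are stiffnesses in
    pN nm^2, ``g`` the plectoneme free-energy coefficient in pN, and
    ``omega0`` the relaxed helical wavenumber in 1/nm.

    When ``sigma_s``/``sigma_p`` are omitted they are derived from branch
    continuity; explicitly supplied values are validated to keep the three
    branches continuous within 1%.

    An RNAP stalls when the net resisting torque (downstream minus
    upstream) reaches ``stall_torque`` (default 10.5 pN nm), or when a flank
    crosses the extreme-density proxy ``sigma_stall`` (default 0.6; upstream
    <= -0.6 for R-loop arrest, downstream >= +0.6 for unmeltable DNA).
    ``k_rot`` is the RNAP counterrotation rate (supercoil transfer across
    the polymerase).
    """

    cs: float = 200.0 / 1.76
    p: float = 50.0 / 1.76
    g: float = 2.0036
    omega0: float = 1.76
    sigma_s: Optional[float] = None
    sigma_p: Optional[float] = None
    stall_torque: float = 10.5
    sigma_stall: float = 0.6
    k_rot: float = 0.2
    torque_window_segments: int = 1
    stall_two_sided: bool = False

    def __post_init__(self) -> None:
        if self.stall_torque <= 0:
            raise ConfigurationError("stall_torque must be positive")
        tau0 = _coexistence_torque(self.cs, self.p, self.g, self.omega0)
        if self.sigma_s is None:
            self.sigma_s = tau0 / (self.cs * self.omega0)
        if self.sigma_p is None:
            self.sigma_p = tau0 / (self.p * self.omega0)
        if not (0 < abs(self.sigma_s) < abs(self.sigma_p)):
            raise ConfigurationError("need 0 < |sigma_s| < |sigma_p|")
        self.validate_continuity()

    @property
    def coexistence_torque(self) -> float:
        return _coexistence_torque(self.cs, self.p, self.g, self.omega0)

    def validate_continuity(self, tol: float = 0.01) -> None:
        """Check the three torque branches agree at sigma_s and sigma_p within tol."""
        tau0 = self.coexistence_torque
        at_s = self.cs * self.omega0 * self.sigma_s
        at_p = self.p * self.omega0 * self.sigma_p
        for name, val in (("sigma_s", at_s), ("sigma_p", at_p)):
            if abs(val - tau0) > tol * max(abs(tau0), 1e-12):
                raise ConfigurationError(
                    f"torque branches discontinuous at {name}: linear branch gives "
                    f"{val:.4f} pN nm vs coexistence {tau0:.4f} pN nm (> {tol:.0%})"
                )


@dataclass
class SimulationConfig:
    """Full model configuration: lattice + genes + topoisomerases + barriers + mechanics."""

    lattice: LatticeConfig
    genes: Sequence[GeneSpec] = field(default_factory=tuple)
    topos: Sequence[TopoSpec] = field(default_factory=tuple)
    barriers: Sequence[BarrierSpec] = field(default_factory=tuple)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.topos = tuple(self.topos)
        self.barriers = tuple(self.barriers)
        self.validate()

    def validate(self) -> None:
        n = self.lattice.n_segments
        seen: dict[int, str] = {}
        for g in self.genes:
            if g.tss_segment < 0 or g.end_segment < 0 or max(g.span) >= n:
                raise ConfigurationError(f"gene {g.name} does not fit the lattice")
            for s in g.span:
                if s in seen:
                    raise ConfigurationError(
                        f"gene {g.name} overlaps {seen[s]} at segment {s}"
                    )
                seen[s] = f"gene {g.name}"
        for b in self.barriers:
            for s in (b.site_a, b.site_b):
                if s < 0 or s >= n:
                    raise ConfigurationError(f"barrier site {s} outside the lattice")
                if s in seen:
                    raise ConfigurationError(
                        f"barrier site {s} overlaps {seen[s]}"
                    )
                seen[s] = "barrier"
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigurationError("gene names must be unique")
        enzymes = [t.enzyme for t in self.topos]
        if len(set(enzymes)) != len(enzymes):
            raise ConfigurationError("at most one TopoSpec per enzyme")

    def gene_index(self, name: str) -> int:
        for i, g in enumerate(self.genes):
            if g.name == name:
                return i
        raise KeyError(name)


@dataclass
class RNAPState:
    """One elongating polymerase: position, progress and stall bookkeeping."""

    id: int
    gene: int
    segment: int
    bp_transcribed: int
    mode: str  # "processive" | "stalled"
    t_start: float
    stall_episodes: list = field(default_factory=list)
    _stall_enter: Optional[float] = None

    def enter_stall(self, t: float) -> None:
        if self._stall_enter is None:
            self._stall_enter = t
        self.mode = "stalled"

    def exit_stall(self, t: float) -> None:
        if self._stall_enter is not None:
            self.stall_episodes.append((self._stall_enter, t))
            self._stall_enter = None
        self.mode = "processive"


@dataclass
class LatticeState:
    """Mutable simulation state: per-segment turns and occupancy, molecule registries."""

    config: SimulationConfig
    turn: np.ndarray
    occupancy: np.ndarray
    occupant_rnap: np.ndarray  # rnap id per segment, -1 if not an RNAP
    rnaps: dict
    looped: np.ndarray
    mrna_count: np.ndarray
    promoter_blocked: np.ndarray
    bp_total: np.ndarray  # cumulative bp transcribed per gene
    t: float = 0.0
    next_rnap_id: int = 0
    counters: dict = field(default_factory=dict)

    def check_invariants(self) -> None:
        """Assert occupancy exclusivity, registry consistency and turn positivity."""
        assert (self.turn >= 0).all(), "negative turn units"
        assert (self.mrna_count >= 0).all(), "negative mRNA count"
        for rid, r in self.rnaps.items():
            assert self.occupancy[r.segment] == RNAP, f"RNAP {rid} segment not marked"
            assert self.occupant_rnap[r.segment] == rid
            g = self.config.genes[r.gene]
            assert r.segment in g.span, f"RNAP {rid} outside gene span"
            assert r.bp_transcribed <= g.length_bp(self.config.lattice.segment_bp)
        n_marked = int((self.occupancy == RNAP).sum())
        assert n_marked == len(self.rnaps), "occupancy / registry mismatch"

    def total_turn(self) -> int:
        return int(self.turn.sum())

    def copy(self) -> "LatticeState":
        return LatticeState(
            config=self.config,
            turn=self.turn.copy(),
            occupancy=self.occupancy.copy(),
            occupant_rnap=self.occupant_rnap.copy(),
            rnaps={
                rid: replace(r, stall_episodes=list(r.stall_episodes))
                for rid, r in self.rnaps.items()
            },
            looped=self.looped.copy(),
            mrna_count=self.mrna_count.copy(),
            promoter_blocked=self.promoter_blocked.copy(),
            bp_total=self.bp_total.copy(),
            t=self.t,
            next_rnap_id=self.next_rnap_id,
            counters={k: dict(v) if isinstance(v, dict) else v for k, v in self.counters.items()},
        )


def build_state(config: SimulationConfig) -> LatticeState:
    """Construct the t = 0 state: uniform initial turns, free DNA except
    permanent / initially-looped barriers, all counters zero."""
    lat = config.lattice
    n = lat.n_segments
    turn = np.full(n, lat.initial_turn_units, dtype=np.int64)
    occ = np.full(n, FREE, dtype=np.int8)
    occ_rnap = np.full(n, -1, dtype=np.int64)
    looped = np.zeros(len(config.barriers), dtype=bool)
    for i, b in enumerate(config.barriers):
        if b.permanent or b.initially_looped:
            occ[b.site_a] = BARRIER
            occ[b.site_b] = BARRIER
            looped[i] = True
    counters = {
        "initiations": np.zeros(len(config.genes), dtype=np.int64),
        "terminations": np.zeros(len(config.genes), dtype=np.int64),
        "topo_catalyses": {t.enzyme: 0 for t in config.topos},
        "boundary_resets": 0,
        "stall_entries": np.zeros(len(config.genes), dtype=np.int64),
        "stall_exits": np.zeros(len(config.genes), dtype=np.int64),
    }
    return LatticeState(
        config=config,
        turn=turn,
        occupancy=occ,
        occupant_rnap=occ_rnap,
        rnaps={},
        looped=looped,
        mrna_count=np.zeros(len(config.genes), dtype=np.int64),
        promoter_blocked=np.zeros(len(config.genes), dtype=bool),
        bp_total=np.zeros(len(config.genes), dtype=np.int64),
        counters=counters,
    )


def region_sigma(
    state: LatticeState,
    segments: Iterable[int],
    exclude_occupied: bool = True,
) -> float:
    """Mean supercoiling density over a set of segments.

    ``(sum turn - n*lk0) / (n*lk0)`` over the set; reduces to
    :func:`sigma_of` for a single segment.  Occupied segments are excluded
    by default (their torsional state is sequestered under the bound
    protein); if every segment in the set is occupied the full set is used.
    """
    segs = np.asarray(list(segments), dtype=np.int64)
    if segs.size == 0:
        raise ValueError("region_sigma: empty segment set")
    if exclude_occupied:
        free = segs[state.occupancy[segs] == FREE]
        if free.size:
            segs = free
    lk0 = state.config.lattice.lk0_units
    n = segs.size
    return (float(state.turn[segs].sum()) - n * lk0) / (n * lk0)


@dataclass
class Trajectory:
    """A recorded sample path: frames at fixed cadence plus a macro event log.

    ``times`` are the frame times (default 1-s cadence).  ``mrna`` is
    (frames, genes); ``rnap_frames[i]`` is an (n_i, 4) int array of
    ``(id, gene, segment, mode)`` with mode 0 = processive, 1 = stalled;
    ``loop_state`` is (frames, barriers).  ``turn`` is the full
    (frames, segments) linking-number profile when profile recording is
    enabled.  ``events`` is a pandas-convertible record array of
    transcription-level events (initiation, termination, report-window
    crossing, loop toggles, promoter block) — micro events (drift, topo,
    boundary) are only logged by the reference engine when asked.

    ``metadata`` carries the full configuration and the seed, sufficient to
    re-run the trajectory bit-identically.
    """

    times: np.ndarray
    mrna: np.ndarray
    rnap_frames: list
    loop_state: np.ndarray
    events: "np.ndarray"
    metadata: dict
    turn: Optional[np.ndarray] = None
    region_means: Optional[dict] = None
    final_counters: Optional[dict] = None

    EVENT_DTYPE = np.dtype(
        [
            ("t", np.float64),
            ("kind", "U16"),
            ("gene", np.int32),
            ("rnap_id", np.int64),
            ("value", np.float64),
        ]
    )

    def events_of(self, kind: str) -> np.ndarray:
        return self.events[self.events["kind"] == kind]

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def validate_cadence(self) -> None:
        dt = np.diff(self.times)
        assert (dt > 0).all(), "frame times must strictly increase"
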