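"""The reaction catalog.

Every stochastic transition of the model is a :class:`ReactionChannel`:
a propensity function of the current state, an ``apply`` effect, and a
``depends_on`` set of state coordinates whose change requires the
propensity to be refreshed.  Coordinates are tuples:
``("turn", k)``, ``("occ", k)``, ``("mrna", g)``, ``("loop", b)``,
``("blocked", g)``.

Catalog (rates refer to the configured constants):

==============  =========================================================
DRIFT           biased down-gradient hop of one linking-number unit to an
                unoccupied neighbour, rate ``k_drift`` per active pair
RANDOM_WALK     gradient-blind unit hop (explicit random-walk mode)
TOPO_BIND/UNBIND pseudo-first-order binding of topo I / gyrase per segment
TOPO_CAT        +1 unit (topo I, sigma < 0) or -2 units (gyrase,
                sigma > 0) at the supercoiling-dependent catalytic rate
INIT            RNAP loading at a free promoter, rate k_i(sigma)
TRANSLOCATE     one-segment RNAP step pushing the entered segment's units
                one segment further downstream (twin-domain bookkeeping);
                doubles as TERMINATE on the gene's final segment
COUNTERROTATE   transfer of one unit across the RNAP, down-gradient
MRNA_DECAY      first-order decay of the gene's mRNA pool
LOOP/UNLOOP     atomic blocking/unblocking of the two barrier sites
BOUNDARY_RELAX  reset of a terminal segment to the chromosomal set point
==============  =========================================================

Total linking number is conserved by every channel except TOPO_CAT
(by exactly the catalytic step) and BOUNDARY_RELAX (a non-conservative
exchange with the unmodelled rest of the chromosome); both book their
deltas into state counters so event logs can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, FrozenSet, List, Optional, Tuple

from . import mechanics
from .state import (
    BARRIER,
    FREE,
    RNAP,
    GeneSpec,
    LatticeState,
    RNAPState,
    SimulationConfig,
    sigma_of,
)

__all__ = ["ReactionChannel", "build_static_channels", "build_rnap_channels", "flank_sigmas", "refresh_modes"]


@dataclass
class ReactionChannel:
    """One reaction: propensity + effect + dependency set.

    ``apply(state, t)`` mutates the state and returns
    ``(writes, structural, event)`` where ``writes`` is the list of
    coordinates changed, ``structural`` signals that the channel list itself
    must be rebuilt (molecules created/destroyed, occupancy changes), and
    ``event`` is an optional ``(kind, gene, rnap_id, value)`` log record.
    """

    kind: str
    key: tuple
    propensity: Callable[[LatticeState], float]
    apply: Callable[[LatticeState, float], tuple]
    depends_on: FrozenSet[tuple] = field(default_factory=frozenset)


def _free_segment(state: LatticeState, k: int) -> None:
    """Release segment k; a blocked promoter's TSS re-seals as a barrier."""
    for g, gene in enumerate(state.config.genes):
        if state.promoter_blocked[g] and gene.tss_segment == k:
            state.occupancy[k] = BARRIER
            return
    state.occupancy[k] = FREE


def _credit_bp(state: LatticeState, g: int, t: float, events: list) -> None:
    gene = state.config.genes[g]
    state.bp_total[g] += state.config.lattice.segment_bp
    if (
        gene.promoter_block_after_bp is not None
        and not state.promoter_blocked[g]
        and state.bp_total[g] >= gene.promoter_block_after_bp
    ):
        state.promoter_blocked[g] = True
        if state.occupancy[gene.tss_segment] == FREE:
            state.occupancy[gene.tss_segment] = BARRIER
        events.append(("promoter_block", g, -1, t))


# ---------------------------------------------------------------- drift


def drift_channels(state: LatticeState) -> List[ReactionChannel]:
    """Biased down-gradient unit hops between neighbouring segments."""
    lat = state.config.lattice
    chans: List[ReactionChannel] = []
    for k in range(lat.n_segments):
        for d in (-1, +1):
            j = k + d
            if not (0 <= j < lat.n_segments):
                continue

            def prop(s, k=k, j=j):
                if s.occupancy[j] != FREE:
                    return 0.0
                return lat.k_drift if s.turn[k] > s.turn[j] else 0.0

            def apply(s, t, k=k, j=j):
                s.turn[k] -= 1
                s.turn[j] += 1
                return ([("turn", k), ("turn", j)], False, None)

            chans.append(
                ReactionChannel(
                    "DRIFT",
                    ("drift", k, d),
                    prop,
                    apply,
                    frozenset({("turn", k), ("turn", j), ("occ", j)}),
                )
            )
    return chans


def random_walk_channels(state: LatticeState) -> List[ReactionChannel]:
    """Gradient-blind unit hops (explicit random-walk diffusion mode).

    Per-direction rate equals ``k_drift = D/dx^2`` so a tagged unit's
    position variance grows as 2 D t, matching the configured macroscopic
    diffusion coefficient.
    """
    lat = state.config.lattice
    chans: List[ReactionChannel] = []
    for k in range(lat.n_segments):
        for d in (-1, +1):
            j = k + d
            if not (0 <= j < lat.n_segments):
                continue

            def prop(s, k=k, j=j):
                if s.occupancy[j] != FREE or s.turn[k] <= 0:
                    return 0.0
                return lat.k_drift

            def apply(s, t, k=k, j=j):
                s.turn[k] -= 1
                s.turn[j] += 1
                return ([("turn", k), ("turn", j)], False, None)

            chans.append(
                ReactionChannel(
                    "RANDOM_WALK",
                    ("rw", k, d),
                    prop,
                    apply,
                    frozenset({("turn", k), ("occ", j)}),
                )
            )
    return chans


# ---------------------------------------------------------------- topoisomerases


def topo_channels(state: LatticeState) -> List[ReactionChannel]:
    cfg = state.config
    lk0 = cfg.lattice.lk0_units
    chans: List[ReactionChannel] = []
    for spec in cfg.topos:
        code = spec.occupancy_code
        for k in range(cfg.lattice.n_segments):

            def p_bind(s, k=k, spec=spec):
                return spec.k_bind if s.occupancy[k] == FREE else 0.0

            def a_bind(s, t, k=k, code=code):
                s.occupancy[k] = code
                return ([("occ", k)], True, None)

            def p_unbind(s, k=k, spec=spec, code=code):
                return spec.k_unbind if s.occupancy[k] == code else 0.0

            def a_unbind(s, t, k=k):
                _free_segment(s, k)
                return ([("occ", k)], True, None)

            def p_cat(s, k=k, spec=spec, code=code):
                if s.occupancy[k] != code:
                    return 0.0
                # suppress events that would overshoot past relaxation
                if spec.catalytic_step_units > 0 and s.turn[k] + spec.catalytic_step_units > lk0:
                    return 0.0
                if spec.catalytic_step_units < 0 and s.turn[k] + spec.catalytic_step_units < lk0:
                    return 0.0
                return mechanics.topo_catalysis_rate(sigma_of(s.turn[k], lk0), spec)

            def a_cat(s, t, k=k, spec=spec):
                s.turn[k] += spec.catalytic_step_units
                s.counters["lk_delta_topo"] = (
                    s.counters.get("lk_delta_topo", 0) + spec.catalytic_step_units
                )
                s.counters["topo_catalyses"][spec.enzyme] += 1
                return ([("turn", k)], False, None)

            chans.append(
                ReactionChannel(
                    "TOPO_BIND", ("bind", spec.enzyme, k), p_bind, a_bind, frozenset({("occ", k)})
                )
            )
            chans.append(
                ReactionChannel(
                    "TOPO_UNBIND",
                    ("unbind", spec.enzyme, k),
                    p_unbind,
                    a_unbind,
                    frozenset({("occ", k)}),
                )
            )
            chans.append(
                ReactionChannel(
                    "TOPO_CAT",
                    ("cat", spec.enzyme, k),
                    p_cat,
                    a_cat,
                    frozenset({("occ", k), ("turn", k)}),
                )
            )
    return chans


# ---------------------------------------------------------------- transcription


def promoter_sigma(state: LatticeState, g: int) -> float:
    gene = state.config.genes[g]
    return sigma_of(int(state.turn[gene.tss_segment]), state.config.lattice.lk0_units)


def initiation_channel(state: LatticeState, g: int) -> ReactionChannel:
    gene = state.config.genes[g]
    tss = gene.tss_segment
    down = tss + gene.direction

    def prop(s):
        if s.promoter_blocked[g]:
            return 0.0
        if s.occupancy[tss] != FREE or s.occupancy[down] != FREE:
            return 0.0
        return mechanics.initiation_rate(promoter_sigma(s, g), gene)

    def apply(s, t):
        rid = s.next_rnap_id
        s.next_rnap_id += 1
        sig = promoter_sigma(s, g)
        # the loading polymerase melts the TSS segment and displaces its
        # linking number one segment downstream (translocation push rule)
        s.turn[down] += s.turn[tss]
        s.turn[tss] = 0
        s.occupancy[tss] = RNAP
        s.occupant_rnap[tss] = rid
        s.rnaps[rid] = RNAPState(
            id=rid, gene=g, segment=tss, bp_transcribed=0, mode="processive", t_start=t
        )
        s.counters["initiations"][g] += 1
        return (
            [("occ", tss), ("turn", tss), ("turn", down)],
            True,
            ("initiation", g, rid, sig),
        )

    return ReactionChannel(
        "INIT",
        ("init", g),
        prop,
        apply,
        frozenset({("occ", tss), ("occ", down), ("turn", tss), ("blocked", g)}),
    )


def translocation_channel(state: LatticeState, rid: int) -> ReactionChannel:
    """One-segment RNAP step; on the gene's final segment this is the
    termination firing (RNAP released, mRNA credited, no turn push)."""
    r = state.rnaps[rid]
    gene = state.config.genes[r.gene]
    lat = state.config.lattice
    rate = gene.k_elong / lat.segment_bp
    d = gene.direction

    def prop(s):
        rr = s.rnaps.get(rid)
        if rr is None or rr.mode != "processive":
            return 0.0
        k = rr.segment
        if k == gene.end_segment:
            return rate  # termination firing
        k1, k2 = k + d, k + 2 * d
        if not (0 <= k2 < lat.n_segments):
            return 0.0
        if s.occupancy[k1] != FREE or s.occupancy[k2] != FREE:
            return 0.0
        return rate

    def apply(s, t):
        rr = s.rnaps[rid]
        k = rr.segment
        events: list = []
        g = rr.gene
        if k == gene.end_segment:
            _free_segment(s, k)
            s.occupant_rnap[k] = -1
            del s.rnaps[rid]
            s.mrna_count[g] += 1
            s.counters["terminations"][g] += 1
            _credit_bp(s, g, t, events)
            ev = ("termination", g, rid, t - rr.t_start)
            return ([("occ", k), ("mrna", g)], True, [ev] + events)
        k1, k2 = k + d, k + 2 * d
        s.turn[k2] += s.turn[k1]
        s.turn[k1] = 0
        _free_segment(s, k)
        s.occupant_rnap[k] = -1
        s.occupancy[k1] = RNAP
        s.occupant_rnap[k1] = rid
        rr.segment = k1
        rr.bp_transcribed += lat.segment_bp
        _credit_bp(s, g, t, events)
        win = gene.report_window_bp
        if win is not None and rr.bp_transcribed - lat.segment_bp < win <= rr.bp_transcribed:
            events.append(("window", g, rid, t - rr.t_start))
        return (
            [("occ", k), ("occ", k1), ("turn", k1), ("turn", k2)],
            True,
            events or None,
        )

    return ReactionChannel("TRANSLOCATE", ("transloc", rid), prop, apply, frozenset())


def counterrotation_channel(state: LatticeState, rid: int) -> ReactionChannel:
    """Counterrotation of the RNAP--mRNA complex, modelled as down-gradient
    diffusion of one unit across the polymerase between its two flanks."""
    lat = state.config.lattice
    k_rot = state.config.mechanics.k_rot

    def _sites(s):
        rr = s.rnaps.get(rid)
        if rr is None:
            return None
        k = rr.segment
        if k - 1 < 0 or k + 1 >= lat.n_segments:
            return None
        return k - 1, k + 1

    def prop(s):
        sites = _sites(s)
        if sites is None:
            return 0.0
        a, b = sites
        if s.turn[a] == s.turn[b]:
            return 0.0
        lo = a if s.turn[a] < s.turn[b] else b
        return k_rot if s.occupancy[lo] == FREE else 0.0

    def apply(s, t):
        a, b = _sites(s)
        hi, lo = (a, b) if s.turn[a] > s.turn[b] else (b, a)
        s.turn[hi] -= 1
        s.turn[lo] += 1
        return ([("turn", hi), ("turn", lo)], False, None)

    return ReactionChannel("COUNTERROTATE", ("rot", rid), prop, apply, frozenset())


def decay_channel(state: LatticeState, g: int) -> ReactionChannel:
    gene = state.config.genes[g]

    def prop(s):
        return gene.mrna_decay_rate * float(s.mrna_count[g])

    def apply(s, t):
        s.mrna_count[g] -= 1
        return ([("mrna", g)], False, None)

    return ReactionChannel("MRNA_DECAY", ("decay", g), prop, apply, frozenset({("mrna", g)}))


# ---------------------------------------------------------------- barriers & boundaries


def loop_channels(state: LatticeState, b: int) -> List[ReactionChannel]:
    spec = state.config.barriers[b]
    if spec.permanent:
        return []
    a_, b_ = spec.site_a, spec.site_b

    def p_loop(s):
        if s.looped[b] or s.occupancy[a_] != FREE or s.occupancy[b_] != FREE:
            return 0.0
        return spec.k_loop

    def a_loop(s, t):
        s.occupancy[a_] = BARRIER
        s.occupancy[b_] = BARRIER
        s.looped[b] = True
        return ([("occ", a_), ("occ", b_), ("loop", b)], True, ("loop", -1, -1, float(b)))

    def p_unloop(s):
        return spec.k_unloop if s.looped[b] else 0.0

    def a_unloop(s, t):
        _free_segment(s, a_)
        _free_segment(s, b_)
        s.looped[b] = False
        return ([("occ", a_), ("occ", b_), ("loop", b)], True, ("unloop", -1, -1, float(b)))

    dep = frozenset({("occ", a_), ("occ", b_), ("loop", b)})
    return [
        ReactionChannel("LOOP", ("loop", b), p_loop, a_loop, dep),
        ReactionChannel("UNLOOP", ("unloop", b), p_unloop, a_unloop, dep),
    ]


def boundary_relax_channels(state: LatticeState) -> List[ReactionChannel]:
    lat = state.config.lattice
    chans = []
    for end, mode in ((0, lat.boundary_left), (lat.n_segments - 1, lat.boundary_right)):
        if mode != "relaxing":
            continue

        def prop(s, end=end):
            return lat.boundary_reset_rate

        def apply(s, t, end=end):
            delta = lat.boundary_target_units - int(s.turn[end])
            s.turn[end] = lat.boundary_target_units
            s.counters["lk_delta_boundary"] = s.counters.get("lk_delta_boundary", 0) + delta
            s.counters["boundary_resets"] += 1
            return ([("turn", end)], False, None)

        chans.append(
            ReactionChannel(
                "BOUNDARY_RELAX", ("boundary", end), prop, apply, frozenset({("turn", end)})
            )
        )
    return chans


# ---------------------------------------------------------------- RNAP mode refresh


def flank_sigmas(state: LatticeState, rid: int) -> Tuple[float, float]:
    """(sigma_up, sigma_down) at the nearest unoccupied segment on each
    side of the RNAP (falling back to the adjacent segment at a closed run)."""
    r = state.rnaps[rid]
    gene = state.config.genes[r.gene]
    lat = state.config.lattice
    d = gene.direction
    out = []
    for side in (-d, +d):  # upstream first
        k = r.segment + side
        chosen = None
        while 0 <= k < lat.n_segments:
            if state.occupancy[k] == FREE:
                chosen = k
                break
            k += side
        if chosen is None:
            chosen = min(max(r.segment + side, 0), lat.n_segments - 1)
        w = state.config.mechanics.torque_window_segments
        if w <= 1:
            out.append(sigma_of(int(state.turn[chosen]), lat.lk0_units))
        else:
            segs = [
                j
                for j in range(chosen, chosen + side * w, side)
                if 0 <= j < lat.n_segments and state.occupancy[j] == FREE
            ] or [chosen]
            tot = sum(int(state.turn[j]) for j in segs)
            n = len(segs)
            out.append((tot - n * lat.lk0_units) / (n * lat.lk0_units))
    return out[0], out[1]


def refresh_modes(state: LatticeState, t: float) -> bool:
    """Re-evaluate every RNAP's stall/processive mode from the current
    flank supercoiling.  Returns True if any mode changed."""
    mech = state.config.mechanics
    changed = False
    for rid, r in state.rnaps.items():
        s_up, s_down = flank_sigmas(state, rid)
        tau = mechanics.net_torque(s_down, s_up, mech)
        mode = mechanics.rnap_mode(tau, s_up, s_down, mech)
        if mode != r.mode:
            changed = True
            if mode == "stalled":
                r.enter_stall(t)
                state.counters["stall_entries"][r.gene] += 1
            else:
                r.exit_stall(t)
                state.counters["stall_exits"][r.gene] += 1
    return changed


# ---------------------------------------------------------------- assembly


def build_static_channels(state: LatticeState) -> List[ReactionChannel]:
    """All channels whose existence does not depend on live RNAP molecules."""
    cfg = state.config
    chans: List[ReactionChannel] = []
    if cfg.lattice.diffusion_mode == "biased":
        chans += drift_channels(state)
    else:
        chans += random_walk_channels(state)
    chans += topo_channels(state)
    chans += boundary_relax_channels(state)
    for g in range(len(cfg.genes)):
        chans.append(initiation_channel(state, g))
        chans.append(decay_channel(state, g))
    for b in range(len(cfg.barriers)):
        chans += loop_channels(state, b)
    return chans


def build_rnap_channels(state: LatticeState) -> List[ReactionChannel]:
    chans: List[ReactionChannel] = []
    for rid in sorted(state.rnaps):
        chans.append(translocation_channel(state, rid))
        chans.append(counterrotation_channel(state, rid))
    return chans
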