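"""Pure response functions: supercoiling -> kinetic rates and RNAP mode.

These are the mechanochemical couplings of the model.  All functions are
pure (no hidden state) and are shared verbatim by the reference engine and
the compiled production kernel.
"""

from __future__ import annotations

import math
from typing import Tuple

from .state import GeneSpec, MechanicsParams, TopoSpec

__all__ = [
    "initiation_rate",
    "torque_marko",
    "net_torque",
    "rnap_mode",
    "topo_catalysis_rate",
]


def initiation_rate(sigma: float, gene: GeneSpec) -> float:
    """Supercoiling-sensitive initiation rate k_i(sigma), in 1/s.

    Piecewise linear and non-increasing: ``k_min`` for relaxed or positively
    supercoiled promoters (sigma >= 0), rising linearly as the promoter
    becomes negatively supercoiled, saturating at ``k_max`` once sigma
    reaches the critical density ``sigma_star`` (promoter melting is
    maximally favoured).
    """
    return _initiation_rate(sigma, gene.k_min, gene.k_max, gene.sigma_star)


def _initiation_rate(sigma: float, k_min: float, k_max: float, sigma_star: float) -> float:
    if sigma >= 0.0:
        return k_min
    if sigma <= sigma_star:
        return k_max
    return k_min + (k_max - k_min) * sigma / sigma_star


def torque_marko(sigma: float, mech: MechanicsParams) -> float:
    """Torque (pN nm) carried by DNA at supercoiling density sigma.

    Three-branch response (Marko's formulation): linear in the pure-twist
    regime, constant at the coexistence torque ``[2 p g/(1 - p/cs)]^(1/2)/omega0``
    while twist buckles into plectonemic writhe, and linear again (slope
    ``p * omega0``) in the fully plectonemic regime.  Odd in sigma.
    """
    return _torque(
        sigma,
        mech.cs * mech.omega0,
        mech.p * mech.omega0,
        mech.coexistence_torque,
        mech.sigma_s,
        mech.sigma_p,
    )


def _torque(
    sigma: float, cs_eff: float, p_eff: float, tau0: float, sigma_s: float, sigma_p: float
) -> float:
    a = abs(sigma)
    if a <= sigma_s:
        return cs_eff * sigma
    if a >= sigma_p:
        return p_eff * sigma
    return math.copysign(tau0, sigma)


def net_torque(sigma_down: float, sigma_up: float, mech: MechanicsParams) -> float:
    """Net resisting torque on an RNAP: downstream torque minus upstream torque.

    Positive values resist translocation (positive supercoiling ahead and/or
    negative behind both load the polymerase); negative values assist.
    """
    return torque_marko(sigma_down, mech) - torque_marko(sigma_up, mech)


def rnap_mode(
    net_tau: float, sigma_up: float, sigma_down: float, mech: MechanicsParams
) -> str:
    """Classify an RNAP as ``"stalled"`` or ``"processive"``.

    Stalled iff the net resisting torque reaches the stall threshold
    (one-sided by default: only resisting, i.e. positive, net torque
    stalls), or a flank crosses the extreme-supercoiling proxy:
    upstream sigma <= -sigma_stall (R-loop arrest) or downstream
    sigma >= +sigma_stall (unmeltable duplex ahead).
    """
    over = (abs(net_tau) if mech.stall_two_sided else net_tau) >= mech.stall_torque
    if over or sigma_up <= -mech.sigma_stall or sigma_down >= mech.sigma_stall:
        return "stalled"
    return "processive"


def topo_catalysis_rate(sigma: float, spec: TopoSpec) -> float:
    """Catalytic firing rate (1/s) of a bound topoisomerase at local sigma.

    Zero on the inactive sign (topo I ignores relaxed/positive DNA, gyrase
    ignores relaxed/negative DNA); on the active sign, a saturating-linear
    response ``kcat_max * min(|sigma|/sigma_half, 1)``.
    """
    return _kcat(sigma, spec.kcat_max, spec.sigma_half, spec.active_sign)


def _kcat(sigma: float, kcat_max: float, sigma_half: float, active_sign: int) -> float:
    if sigma * active_sign <= 0.0:
        return 0.0
    a = abs(sigma)
    if sigma_half <= 0.0:
        return kcat_max
    return kcat_max * min(a / sigma_half, 1.0)
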