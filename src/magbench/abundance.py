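"""Ranked species-abundance distributions for mock communities.

Five distribution shapes are supported: equal abundance, logarithmic decay,
exponential decay, and both decays with *abundance plateaus* — consecutive
pairs of ranks sharing one abundance level.  Decay profiles are calibrated
so that the lowest-ranked species sits exactly at a configurable abundance
floor (default 0.009, the smallest relative abundance used in the benchmark
design), and every profile is normalized to sum to one.

Functional forms
----------------
exponential decay   a_i ∝ r**(i-1),        0 < r < 1
logarithmic decay   a_i ∝ C - ln(i),       C > ln(n)

The decay parameter (r or C) is solved by bracketed root finding so that
the normalized minimum equals the floor to within 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleParameterError

KINDS = ("equal", "log_decay", "exp_decay", "log_decay_plateau", "exp_decay_plateau")
DECAY_KINDS = ("log_decay", "exp_decay")
PLATEAU_KINDS = ("log_decay_plateau", "exp_decay_plateau")

DEFAULT_FLOOR = 0.009


@dataclass(frozen=True)
class AbundanceProfile:
    """A ranked relative-abundance vector for one distribution shape."""

    kind: str
    abundances: tuple[float, ...]
    n_species: int
    floor: float
    decay_param: float | None = None

    def as_array(self) -> np.ndarray:
        return np.asarray(self.abundances, dtype=float)


def _exp_vector(r: float, n: int) -> np.ndarray:
    a = r ** np.arange(n, dtype=float)
    return a / a.sum()


def _log_vector(c: float, n: int) -> np.ndarray:
    a = c - np.log(np.arange(1, n + 1, dtype=float))
    return a / a.sum()


def _check_decay_args(kind: str, n_species: int, floor: float) -> None:
    if kind not in DECAY_KINDS:
        raise ValueError(f"unknown decay kind {kind!r}; expected one of {DECAY_KINDS}")
    if n_species < 2:
        raise ValueError("n_species must be at least 2")
    if not 0.0 < floor < 1.0 / n_species:
        raise InfeasibleParameterError(
            f"floor {floor} infeasible for {kind} over {n_species} ranks; "
            f"need 0 < floor < 1/n = {1.0 / n_species:.6g}"
        )


def calibrate_decay(kind: str, n_species: int, floor: float = DEFAULT_FLOOR) -> float:
    """Solve for the decay parameter whose normalized minimum equals *floor*.

    The minimum of the normalized vector is monotone in the parameter
    (increasing in r for the geometric form, increasing in C for the
    logarithmic form), so a bracketed root is unique.
    """
    _check_decay_args(kind, n_species, floor)
    if kind == "exp_decay":
        if n_species == 2:
            return floor / (1.0 - floor)  # closed form: r/(1+r) = floor
        f = lambda r: _exp_vector(r, n_species)[-1] - floor
        lo, hi = 1e-12, 1.0 - 1e-12
    else:
        f = lambda c: _log_vector(c, n_species)[-1] - floor
        lo = np.log(n_species) + 1e-12
        hi = np.log(n_species) + 1.0
        while f(hi) < 0:  # min -> 1/n as C -> inf, so a bracket always exists
            hi *= 2.0
            if hi > 1e12:
                raise InfeasibleParameterError(
                    f"no bracket found for {kind} with n={n_species}, floor={floor}"
                )
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))


def make_profile(
    kind: str,
    n_species: int,
    floor: float = DEFAULT_FLOOR,
    abundances: "np.ndarray | None" = None,
) -> AbundanceProfile:
    """Build a normalized ranked abundance profile.

    Deterministic — no RNG is involved.  An explicit ``abundances`` vector
    overrides the functional form so externally specified designs can be
    replayed verbatim; it is only normalized and checked for monotonicity.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown abundance kind {kind!r}; expected one of {KINDS}")
    if n_species < 2:
        raise ValueError("n_species must be at least 2")

    if abundances is not None:
        a = np.asarray(abundances, dtype=float)
        if a.shape != (n_species,):
            raise ValueError(f"explicit abundance vector has length {a.size}, expected {n_species}")
        if np.any(a <= 0):
            raise ValueError("explicit abundances must be positive")
        if np.any(np.diff(a) > 0):
            raise ValueError("explicit abundances must be non-increasing by rank")
        a = a / a.sum()
        return AbundanceProfile(kind, tuple(a.tolist()), n_species, float(a[-1]), None)

    if kind == "equal":
        a = np.full(n_species, 1.0 / n_species)
        return AbundanceProfile(kind, tuple(a.tolist()), n_species, 1.0 / n_species, None)

    if kind in PLATEAU_KINDS:
        base_kind = kind.replace("_plateau", "")
        base = make_profile(base_kind, n_species, floor)
        return apply_plateaus(base)

    param = calibrate_decay(kind, n_species, floor)
    a = _exp_vector(param, n_species) if kind == "exp_decay" else _log_vector(param, n_species)
    return AbundanceProfile(kind, tuple(a.tolist()), n_species, floor, param)


def apply_plateaus(profile: AbundanceProfile) -> AbundanceProfile:
    """Turn a decay profile into its plateau variant (paired equal ranks).

    The plateau shape over n ranks uses a decay curve over n/2 levels, each
    level occupied by a consecutive pair of species, renormalized to sum to
    one.  The half-length curve is calibrated at twice the floor so the
    renormalized minimum still equals the original floor.
    """
    if profile.kind not in DECAY_KINDS:
        raise ValueError(f"plateaus apply to decay profiles only, got {profile.kind!r}")
    n = profile.n_species
    if n % 2 != 0:
        raise ValueError(f"plateau profiles need an even number of species, got {n}")
    levels = n // 2
    param = calibrate_decay(profile.kind, levels, 2.0 * profile.floor)
    lv = _exp_vector(param, levels) if profile.kind == "exp_decay" else _log_vector(param, levels)
    a = np.repeat(lv, 2) / 2.0
    return AbundanceProfile(
        kind=profile.kind + "_plateau",
        abundances=tuple(a.tolist()),
        n_species=n,
        floor=profile.floor,
        decay_param=param,
    )
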