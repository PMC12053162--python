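"""Closed-form gradient-echo signal models for nonexponential transverse decay.

Magnetic inclusions (iron-rich cells, vessels, myelin) dephase spins at the
microscopic scale and make the gradient-echo magnitude decay nonexponential:
at short echo times the log-signal is quadratic with curvature set by the
Larmor-frequency variance ``Omega2`` (rad^2/s^2), while at long echo times
it is linear with rate ``R2_micro`` (s^-1).  The transition happens on a
characteristic timescale ``t_c = R2_micro / Omega2``.

Four models of the full decay are implemented, all sharing the multiplicative
nanoscale relaxation factor ``exp(-R2_nano * TE)`` and a caller-supplied
macroscopic attenuation ``F_macro(TE)``:

``exponential``
    ``S = S0 * exp(-R2_star * TE)`` with ``R2_star = R2_micro + R2_nano``.
``pade``
    A rational (Padé) interpolation between the Gaussian and exponential
    asymptotes: exponent ``-(Omega2*TE^2/2) / (1 + Omega2*TE/(2*R2_micro))``.
``anderson_weiss``
    Gaussian phase accumulation with an exponential frequency
    autocorrelation: exponent ``-(R2_micro^2/Omega2) * (kt + exp(-kt) - 1)``
    with ``kt = (Omega2/R2_micro) * TE``.
``jensen_chandra``
    Gaussian phase accumulation with the autocorrelation implied by free
    Gaussian diffusion around spherical perturbers: exponent
    ``-(R2_micro^2/Omega2) * (kt + 1 - sqrt(1 + 2*kt))``.  The square-root
    term makes the approach to the exponential asymptote slow (a sqrt(TE)
    sub-leading correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "RelaxationParams",
    "EchoSchedule",
    "eval_exponential",
    "eval_pade",
    "eval_anderson_weiss",
    "eval_jensen_chandra",
    "evaluate_model",
    "transition_time",
    "MODEL_EVALUATORS",
]


@dataclass
class RelaxationParams:
    """Relaxation parameters of one voxel.

    Parameters
    ----------
    S0 : float
        Signal amplitude at TE=0, arbitrary units; must be positive.
    R2_micro : float
        Long-time microscopic relaxation rate, s^-1.
    Omega2 : float
        Variance of the inclusion-induced Larmor frequency offsets,
        rad^2/s^2; sets the short-time Gaussian decay.
    R2_nano : float
        Nanoscale (molecular) relaxation rate, s^-1; fixed, never fitted.
    R2_star : float or None
        Total exponential rate, s^-1.  If None it defaults to
        ``R2_micro + R2_nano`` (exponential model only).
    """

    S0: float
    R2_micro: float = 0.0
    Omega2: float = 0.0
    R2_nano: float = 0.0
    R2_star: float | None = None

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError(f"S0 must be positive, got {self.S0}")
        for name in ("R2_micro", "Omega2", "R2_nano"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.R2_star is None:
            self.R2_star = self.R2_micro + self.R2_nano

    @property
    def t_c(self) -> float:
        """Gaussian-to-exponential transition time, s (inf when Omega2=0)."""
        if self.Omega2 == 0:
            return float("inf")
        return self.R2_micro / self.Omega2


@dataclass
class EchoSchedule:
    """Echo times of a multi-echo gradient-echo acquisition.

    Parameters
    ----------
    echo_times : ndarray
        Echo times in seconds, strictly increasing, all positive.
        Repetitions concatenated along the echo axis are allowed via
        ``n_repetitions``; in that case ``echo_times`` holds the
        concatenated vector (the base schedule tiled).
    f_macro : ndarray or None
        Per-echo macroscopic attenuation factors in (0, 1], same length as
        ``echo_times``.  Defaults to unity (macroscopic-field correction
        assumed done upstream or negligible).
    n_repetitions : int
        Number of concatenated repetitions represented by ``echo_times``.
    """

    echo_times: np.ndarray
    f_macro: np.ndarray | None = None
    n_repetitions: int = 1

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.echo_times.ndim != 1 or self.echo_times.size == 0:
            raise ValueError("echo_times must be a non-empty 1-D vector")
        if np.any(self.echo_times <= 0):
            raise ValueError("echo times must all be positive")
        n_rep = self.n_repetitions
        base = self.echo_times[: self.echo_times.size // max(n_rep, 1)]
        if n_rep == 1 and np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if n_rep > 1 and np.any(np.diff(base) <= 0):
            raise ValueError("per-repetition echo_times must be strictly increasing")
        if self.f_macro is None:
            self.f_macro = np.ones_like(self.echo_times)
        else:
            self.f_macro = np.asarray(self.f_macro, dtype=float)
            if self.f_macro.shape != self.echo_times.shape:
                raise ValueError(
                    "f_macro length {} does not match echo_times length {}".format(
                        self.f_macro.size, self.echo_times.size
                    )
                )
            if np.any((self.f_macro <= 0) | (self.f_macro > 1)):
                raise ValueError("f_macro entries must lie in (0, 1]")

    @property
    def n_echoes(self) -> int:
        return self.echo_times.size

    @classmethod
    def default(cls, n_echoes: int = 16, te1: float = 1.25e-3,
                dte: float = 1.2e-3, n_repetitions: int = 1) -> "EchoSchedule":
        """The acquisition default: 16 echoes from 1.25 ms, 1.2 ms apart."""
        te = te1 + dte * np.arange(n_echoes)
        if n_repetitions > 1:
            te = np.tile(te, n_repetitions)
        return cls(echo_times=te, n_repetitions=n_repetitions)

    def tiled(self, n_repetitions: int) -> "EchoSchedule":
        """Return a schedule with the base echoes tiled n_repetitions times."""
        if self.n_repetitions != 1:
            raise ValueError("schedule is already tiled")
        return EchoSchedule(
            echo_times=np.tile(self.echo_times, n_repetitions),
            f_macro=np.tile(self.f_macro, n_repetitions),
            n_repetitions=n_repetitions,
        )


def _common_factor(params: RelaxationParams, sched: EchoSchedule) -> np.ndarray:
    te = sched.echo_times
    return params.S0 * np.exp(-params.R2_nano * te) * sched.f_macro


def _check_micro(params: RelaxationParams) -> None:
    if params.Omega2 > 0 and params.R2_micro <= 0:
        raise ValueError(
            "Omega2 > 0 requires R2_micro > 0: the Gaussian-to-exponential "
            "transition is undefined at zero long-time rate"
        )


def eval_exponential(params: RelaxationParams, sched: EchoSchedule) -> np.ndarray:
    """Exponential decay ``S0 * exp(-R2_star*TE) * F_macro(TE)``."""
    te = sched.echo_times
    return params.S0 * np.exp(-params.R2_star * te) * sched.f_macro


def eval_pade(params: RelaxationParams, sched: EchoSchedule) -> np.ndarray:
    """Padé interpolation between Gaussian and exponential decay."""
    _check_micro(params)
    te = sched.echo_times
    if params.Omega2 == 0:
        micro = np.exp(-params.R2_micro * te)
    else:
        micro = np.exp(
            -(params.Omega2 * te**2 / 2.0)
            / (1.0 + params.Omega2 * te / (2.0 * params.R2_micro))
        )
    return _common_factor(params, sched) * micro


def eval_anderson_weiss(params: RelaxationParams, sched: EchoSchedule) -> np.ndarray:
    """Anderson-Weiss decay (exponential frequency autocorrelation)."""
    _check_micro(params)
    te = sched.echo_times
    if params.Omega2 == 0:
        micro = np.exp(-params.R2_micro * te)
    else:
        kt = (params.Omega2 / params.R2_micro) * te
        # expm1 keeps the short-time (kt -> 0) limit accurate.
        micro = np.exp(
            -(params.R2_micro**2 / params.Omega2) * (kt + np.expm1(-kt))
        )
    return _common_factor(params, sched) * micro


def eval_jensen_chandra(params: RelaxationParams, sched: EchoSchedule) -> np.ndarray:
    """Jensen-Chandra decay (Gaussian-diffusion frequency autocorrelation)."""
    _check_micro(params)
    te = sched.echo_times
    if params.Omega2 == 0:
        micro = np.exp(-params.R2_micro * te)
    else:
        kt = (params.Omega2 / params.R2_micro) * te
        # kt + 1 - sqrt(1 + 2 kt), written via sqrt1pm1-style guard for
        # accuracy at kt << 1 where the leading term is kt^2/2.
        root = np.sqrt(1.0 + 2.0 * kt)
        bracket = np.where(
            kt < 1e-6,
            kt**2 / 2.0 - kt**3 / 2.0,
            kt + 1.0 - root,
        )
        micro = np.exp(-(params.R2_micro**2 / params.Omega2) * bracket)
    return _common_factor(params, sched) * micro


MODEL_EVALUATORS: dict[str, Callable[[RelaxationParams, EchoSchedule], np.ndarray]] = {
    "exponential": eval_exponential,
    "pade": eval_pade,
    "anderson_weiss": eval_anderson_weiss,
    "jensen_chandra": eval_jensen_chandra,
}


def evaluate_model(model: str, params: RelaxationParams,
                   sched: EchoSchedule) -> np.ndarray:
    """Evaluate a named signal model on an echo schedule."""
    try:
        fn = MODEL_EVALUATORS[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; choose from {sorted(MODEL_EVALUATORS)}"
        ) from None
    return fn(params, sched)


def transition_time(params: RelaxationParams) -> float:
    """Gaussian-to-exponential transition time ``t_c = R2_micro / Omega2`` (s).

    Raises
    ------
    ValueError
        If ``Omega2`` is zero (the decay is purely exponential and the
        transition time is undefined/infinite).
    """
    if params.Omega2 <= 0:
        raise ValueError("transition time undefined for Omega2 = 0")
    return params.R2_micro / params.Omega2
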