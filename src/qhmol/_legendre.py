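"""Associated Legendre functions of both kinds at complex polar angle.

The polar factor of a rovibrational eigenfunction is
``Theta(theta) = B1 * P_J^m(cos theta) + B2 * Q_J^m(cos theta)``.  Complex
quantum trajectories evaluate ``Theta`` and its first two theta-derivatives at
complex ``theta``, which no installed special-function library provides for
the second kind (``scipy.special.lpmv`` is real-only).  Closed forms are
therefore generated symbolically once per ``(J, m, kind)`` and compiled to
numpy callables.

Branch conventions
------------------
* First kind (Ferrers, Condon–Shortley phase):
  ``P_J^m(cos theta) = (-1)^m sin(theta)^m d^m P_J(x)/dx^m |_{x=cos theta}``.
  This is entire in ``theta``.
* Second kind: ``Q_J(z)`` is taken on the complex plane cut along the real
  segment ``[-1, 1]`` — the branch that decays like ``z^{-(J+1)}`` for large
  ``|z|`` — via ``Q_0(z) = log((z+1)/(z-1)) / 2`` (principal logarithm) and
  ``Q_J = P_J Q_0 - W_{J-1}`` with ``W_{J-1} = sum_k P_{k-1} P_{J-k} / k``.
  For ``m > 0``, ``Q_J^m(z) = (z^2-1)^{m/2} d^m Q_J/dz^m`` (Hobson), with the
  principal power.  As a function of ``theta`` this branch is analytic in
  each half-plane ``Im(theta) > 0`` and ``Im(theta) < 0`` (the cut image is
  the real ``theta`` axis), which is where the spin-carrying trajectories
  live.  On real ``theta`` the evaluation returns the principal-branch limit,
  which differs from the real Ferrers ``Q`` by an additive multiple of the
  first-kind solution; both are valid angular solutions.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable

import numpy as np
import sympy as sp

__all__ = ["legendre_theta_callables", "legendre_p_theta", "legendre_q_theta"]


def _legendre_q_x(J: int, x: sp.Symbol) -> sp.Expr:
    """Second-kind Legendre function Q_J on the cut plane, symbolic in x."""
    q0 = sp.log((x + 1) / (x - 1)) / 2
    if J == 0:
        return q0
    w = sum(sp.legendre(k - 1, x) * sp.legendre(J - k, x) / sp.Integer(k) for k in range(1, J + 1))
    return sp.legendre(J, x) * q0 - w


@lru_cache(maxsize=None)
def _theta_exprs(J: int, m: int, kind: str):
    """Symbolic (Theta, dTheta/dtheta, d2Theta/dtheta2) for one branch."""
    if m < 0 or m > J:
        raise ValueError(f"require 0 <= m <= J, got (J, m) = ({J}, {m})")
    th = sp.Symbol("theta")
    x = sp.Symbol("x")
    if kind == "first_kind":
        base = sp.diff(sp.legendre(J, x), x, m)
        expr = (-1) ** m * sp.sin(th) ** m * base.subs(x, sp.cos(th))
    elif kind == "second_kind":
        base = sp.diff(_legendre_q_x(J, x), x, m)
        expr = base.subs(x, sp.cos(th))
        if m:
            # principal power of (cos^2 theta - 1); single-valued log-derivative
            expr = sp.exp(sp.Rational(m, 2) * sp.log(sp.cos(th) ** 2 - 1)) * expr
    else:
        raise ValueError(f"unknown Legendre kind {kind!r}")
    expr = sp.simplify(expr) if J <= 3 else expr
    d1 = sp.diff(expr, th)
    d2 = sp.diff(d1, th)
    return th, expr, d1, d2


@lru_cache(maxsize=None)
def legendre_theta_callables(J: int, m: int, kind: str) -> tuple[Callable, Callable, Callable]:
    """Compiled (value, first, second derivative) callables of theta.

    Each accepts scalar or array ``theta``, real or complex, and returns
    complex values.
    """
    th, expr, d1, d2 = _theta_exprs(J, m, kind)

    def compile_(e: sp.Expr) -> Callable:
        if e.is_constant():
            value = complex(e)
            return lambda t, _v=value: np.broadcast_to(_v, np.shape(t)).copy() if np.ndim(t) else _v
        fn = sp.lambdify(th, e, modules="numpy")
        return lambda t, _f=fn: _f(np.asarray(t, dtype=complex) if np.ndim(t) else complex(t))

    return compile_(expr), compile_(d1), compile_(d2)


def legendre_p_theta(J: int, m: int, theta):
    """First-kind associated Legendre ``P_J^m(cos theta)`` for complex theta."""
    return legendre_theta_callables(J, m, "first_kind")[0](theta)


def legendre_q_theta(J: int, m: int, theta):
    """Second-kind associated Legendre ``Q_J^m(cos theta)``, cut-plane branch."""
    return legendre_theta_callables(J, m, "second_kind")[0](theta)
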