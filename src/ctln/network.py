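"""CTLN construction and exact fixed-point enumeration.

A CTLN is the threshold-linear network

    dx_i/dt = -x_i + [sum_j W_ij x_j + theta]_+

whose weights are read off a directed graph G:

    W_ij = 0 on the diagonal, -1 + eps when j -> i, and -1 - delta when
    there is no edge j -> i.

With delta > 0, theta > 0 and 0 < eps < delta/(delta+1) (the *legal
range*) the network is inhibition-dominated.  Fixed points are labeled by
their support sigma (the set of active neurons); within the support the
fixed point solves x_sigma = theta (I - W_sigma)^{-1} 1_sigma, and
membership of sigma in FP(G) is a strict sign condition.  Membership is
decided in exact rational arithmetic whenever the parameters are rational,
so no sign can silently flip; a floating-point backend with a strictness
tolerance is available as well.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .digraph import Digraph, induced_subgraph

__all__ = [
    "CTLNParams",
    "DegeneracyError",
    "IllegalParameterError",
    "FixedPoint",
    "FPSet",
    "build_W",
    "build_W_exact",
    "fixed_point_value",
    "is_fixed_point_support",
    "enumerate_FP",
    "stability",
    "check_parameter_independence",
    "STANDARD_GRID",
]

Number = Fraction | float


class DegeneracyError(ArithmeticError):
    """A fixed-point sign condition landed exactly on zero (or I - W_sigma
    is singular).  The theory assumes nondegeneracy; we refuse to decide."""


class IllegalParameterError(ValueError):
    """Parameters outside the legal range delta>0, theta>0, 0<eps<delta/(delta+1)."""


def _to_number(x) -> Number:
    """Fractions stay exact; ints and decimal strings become Fractions;
    floats stay floats (callers lose the exact backend then)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)
    return float(x)


@dataclass(frozen=True)
class CTLNParams:
    """The (eps, delta, theta) triple defining a CTLN.

    eps is the excitation offset (edge weight -1+eps), delta the inhibition
    offset (non-edge weight -1-delta), theta the constant external drive.
    Values given as int, Fraction or decimal string are kept exact.
    """

    eps: Number = Fraction(1, 4)
    delta: Number = Fraction(1, 2)
    theta: Number = Fraction(1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "eps", _to_number(self.eps))
        object.__setattr__(self, "delta", _to_number(self.delta))
        object.__setattr__(self, "theta", _to_number(self.theta))

    @property
    def is_exact(self) -> bool:
        return all(isinstance(v, Fraction) for v in (self.eps, self.delta, self.theta))

    @property
    def is_legal(self) -> bool:
        e, d, t = self.eps, self.delta, self.theta
        return d > 0 and t > 0 and 0 < e < d / (d + 1)

    def require_legal(self) -> "CTLNParams":
        if not self.is_legal:
            raise IllegalParameterError(
                f"(eps, delta, theta) = ({self.eps}, {self.delta}, {self.theta}) "
                "violates delta>0, theta>0, 0<eps<delta/(delta+1)"
            )
        return self

    @classmethod
    def standard(cls) -> "CTLNParams":
        """theta = 1, eps = 0.25, delta = 0.5."""
        return cls(Fraction(1, 4), Fraction(1, 2), Fraction(1))

    @classmethod
    def high_inhibition(cls) -> "CTLNParams":
        """The higher-inhibition regime theta = 1, eps = 0.25, delta = 1.25."""
        return cls(Fraction(1, 4), Fraction(5, 4), Fraction(1))

    def floats(self) -> tuple[float, float, float]:
        return float(self.eps), float(self.delta), float(self.theta)


#: A small legal parameter grid used for parameter-independence checks.
#: The points are generic: e.g. (eps, delta) = (2/5, 1) is avoided because
#: I - W_sigma becomes exactly singular on some supports there.
STANDARD_GRID: tuple[CTLNParams, ...] = (
    CTLNParams.standard(),
    CTLNParams(Fraction(1, 10), Fraction(3, 10), Fraction(1)),
    CTLNParams.high_inhibition(),
    CTLNParams(Fraction(7, 20), Fraction(9, 10), Fraction(2)),
)


# ---------------------------------------------------------------------------
# Weight matrices
# ---------------------------------------------------------------------------

def build_W(G: Digraph, params: CTLNParams, allow_illegal: bool = False) -> np.ndarray:
    """The n x n CTLN weight matrix as floats (row i, column j = j's effect on i)."""
    if not allow_illegal:
        params.require_legal()
    e, d, _ = params.floats()
    n = G.n
    W = np.full((n, n), -1.0 - d)
    for j, i in G.edges:  # edge j -> i
        W[i - 1, j - 1] = -1.0 + e
    np.fill_diagonal(W, 0.0)
    return W


def build_W_exact(
    G: Digraph, params: CTLNParams, allow_illegal: bool = False
) -> list[list[Fraction]]:
    if not allow_illegal:
        params.require_legal()
    if not params.is_exact:
        raise ValueError("exact weight matrix requires rational parameters")
    e, d = params.eps, params.delta
    n = G.n
    W = [[-1 - d] * n for _ in range(n)]
    for j, i in G.edges:
        W[i - 1][j - 1] = -1 + e
    for i in range(n):
        W[i][i] = Fraction(0)
    return W


# ---------------------------------------------------------------------------
# Exact linear solve (Gaussian elimination over the rationals)
# ---------------------------------------------------------------------------

def _solve_exact(A: list[list[Fraction]], b: list[Fraction]) -> list[Fraction]:
    """Solve A x = b exactly; raises DegeneracyError when A is singular."""
    m = len(A)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(m):
        piv = next((r for r in range(col, m) if M[r][col] != 0), None)
        if piv is None:
            raise DegeneracyError("singular matrix I - W_sigma")
        M[col], M[piv] = M[piv], M[col]
        inv = M[col][col]
        M[col] = [v / inv for v in M[col]]
        for r in range(m):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [vr - f * vc for vr, vc in zip(M[r], M[col])]
    return [M[r][m] for r in range(m)]


# ---------------------------------------------------------------------------
# Fixed points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint:
    """A CTLN fixed point: support, value vector, and stability."""

    support: frozenset[int]
    value: tuple  # length-n vector, zero off the support
    stable: bool | None = None

    @property
    def size(self) -> int:
        return len(self.support)


@dataclass(frozen=True)
class FPSet:
    """FP(G): the set of fixed-point supports of a CTLN, with values."""

    graph: Digraph
    params: CTLNParams
    fixed_points: tuple[FixedPoint, ...]

    @property
    def supports(self) -> tuple[frozenset[int], ...]:
        return tuple(fp.support for fp in self.fixed_points)

    def support_strings(self) -> tuple[str, ...]:
        return tuple("".join(map(str, sorted(s))) for s in self.fixed_points_sorted())

    def fixed_points_sorted(self) -> tuple[frozenset[int], ...]:
        return tuple(sorted(self.supports, key=lambda s: (len(s), sorted(s))))

    def __len__(self) -> int:
        return len(self.fixed_points)

    def __contains__(self, sigma) -> bool:
        return frozenset(sigma) in set(self.supports)


FLOAT_STRICTNESS_TOL = 1e-9


def fixed_point_value(
    G: Digraph,
    sigma: Iterable[int],
    params: CTLNParams,
    exact: bool | None = None,
    allow_illegal: bool = False,
):
    """The candidate fixed point with support sigma: theta (I-W_sigma)^{-1} 1.

    Returns a length-n vector (Fractions when exact, else floats) that is
    zero off sigma.  The entries on sigma need not be positive; positivity
    is what :func:`is_fixed_point_support` checks.
    """
    sig = sorted(set(sigma))
    if not sig:
        raise ValueError("sigma must be non-empty")
    if not set(sig) <= set(G.vertices):
        raise ValueError(f"sigma {sig} is not a subset of the vertices")
    if exact is None:
        exact = params.is_exact
    if exact:
        W = build_W_exact(G, params, allow_illegal=allow_illegal)
        A = [
            [(1 if a == b else 0) - W[i - 1][j - 1] for b, j in enumerate(sig)]
            for a, i in enumerate(sig)
        ]
        xs = _solve_exact(A, [params.theta] * len(sig))
        x = [Fraction(0)] * G.n
    else:
        Wf = build_W(G, params, allow_illegal=allow_illegal)
        idx = [i - 1 for i in sig]
        A = np.eye(len(sig)) - Wf[np.ix_(idx, idx)]
        try:
            xs = np.linalg.solve(A, float(params.theta) * np.ones(len(sig)))
        except np.linalg.LinAlgError as err:
            raise DegeneracyError("singular matrix I - W_sigma") from err
        x = [0.0] * G.n
    for i, v in zip(sig, xs):
        x[i - 1] = v
    return x


def is_fixed_point_support(
    G: Digraph,
    sigma: Iterable[int],
    params: CTLNParams,
    exact: bool | None = None,
    allow_illegal: bool = False,
) -> bool:
    """Is sigma the support of a fixed point of the CTLN on G?

    True iff every on-support value is strictly positive and every off-
    support neuron k receives strictly negative net input
    sum_{j in sigma} W_kj x_j + theta < 0, so [.]_+ pins x_k at 0.
    Exact zeros raise :class:`DegeneracyError` rather than deciding.
    """
    sig = sorted(set(sigma))
    if exact is None:
        exact = params.is_exact
    x = fixed_point_value(G, sig, params, exact=exact, allow_illegal=allow_illegal)

    def strictly(v, positive: bool) -> bool:
        if exact:
            if v == 0:
                raise DegeneracyError(f"degenerate zero for sigma={sig} on graph {G!r}")
            return v > 0 if positive else v < 0
        if abs(v) < FLOAT_STRICTNESS_TOL:
            raise DegeneracyError(f"value within tolerance of zero for sigma={sig}")
        return v > 0 if positive else v < 0

    if not all(strictly(x[i - 1], positive=True) for i in sig):
        return False
    if exact:
        W = build_W_exact(G, params, allow_illegal=allow_illegal)
        theta = params.theta
    else:
        W = build_W(G, params, allow_illegal=allow_illegal)
        theta = float(params.theta)
    for k in G.vertices:
        if k in sig:
            continue
        s = sum(W[k - 1][j - 1] * x[j - 1] for j in sig) + theta
        if not strictly(s, positive=False):
            return False
    return True


def stability(
    G: Digraph,
    sigma: Iterable[int],
    params: CTLNParams,
    tol: float = 1e-9,
    allow_illegal: bool = False,
) -> str:
    """'stable' or 'unstable' for the fixed point supported on sigma.

    Decided by the eigenvalues of -I + W_sigma (the Jacobian on the
    support; the off-support conditions are strict by nondegeneracy).
    """
    sig = sorted(set(sigma))
    W = build_W(G, params, allow_illegal=allow_illegal)
    idx = [i - 1 for i in sig]
    J = -np.eye(len(sig)) + W[np.ix_(idx, idx)]
    re = np.linalg.eigvals(J).real
    if np.any(np.abs(re) < tol):
        raise DegeneracyError(
            f"eigenvalue real part within {tol} of zero for sigma={sig}"
        )
    return "stable" if np.all(re < 0) else "unstable"


def enumerate_FP(
    G: Digraph,
    params: CTLNParams | None = None,
    exact: bool | None = None,
    with_values: bool = True,
    allow_illegal: bool = False,
) -> FPSet:
    """Brute-force FP(G): test all 2^n - 1 supports.

    Supports are scanned in lexicographic order by (size, labels) so the
    report order is reproducible.
    """
    params = params or CTLNParams.standard()
    fps = []
    for size in range(1, G.n + 1):
        for sig in itertools.combinations(G.vertices, size):
            if is_fixed_point_support(G, sig, params, exact=exact, allow_illegal=allow_illegal):
                support = frozenset(sig)
                if with_values:
                    val = tuple(
                        fixed_point_value(G, sig, params, exact=exact, allow_illegal=allow_illegal)
                    )
                    stab = stability(G, sig, params, allow_illegal=allow_illegal) == "stable"
                else:
                    val, stab = (), None
                fps.append(FixedPoint(support, val, stab))
    return FPSet(G, params, tuple(fps))


def check_parameter_independence(
    G: Digraph, grid: Sequence[CTLNParams] = STANDARD_GRID
) -> tuple[bool, tuple[CTLNParams, CTLNParams] | None]:
    """Is FP(G) identical across a grid of legal parameter points?

    Returns (True, None) when all agree, else (False, (p1, p2)) naming two
    differing points.
    """
    for p in grid:
        p.require_legal()
    sets = [
        (p, frozenset(enumerate_FP(G, p, with_values=False).supports)) for p in grid
    ]
    first_p, first = sets[0]
    for p, s in sets[1:]:
        if s != first:
            return False, (first_p, p)
    return True, None
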