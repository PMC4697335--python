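"""Elemental balancing of fermentation equations.

Given substrate and product species with known {C,H,O,N} formulas, solve for
stoichiometric coefficients with a chosen reference substrate fixed at 1.
The balance is an exact rational linear system (sympy); when the solution
space is one-dimensional after optional fixed-ratio constraints, the minimal
non-negative all-integer member is selected — the convention that reproduces
the fructoselysine-alone fermentation equation without extra assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import lcm
from typing import Mapping, Sequence

import sympy as sp

from .chem import ELEMENTS, Metabolite
from .errors import BalanceAmbiguityError, BalanceInfeasibleError

#: Largest coefficient considered when enumerating integer members of a
#: one-dimensional solution family. Fermentation stoichiometries live far
#: below this.
MAX_INTEGER_COEFF = 60


@dataclass(frozen=True)
class BalancedEquation:
    """A (proposed) fermentation equation with rational coefficients.

    ``solution_dim`` is the dimension of the elemental-balance solution space
    the equation was selected from (0 = unique given the reference).
    """

    substrates: tuple[tuple[Metabolite, Fraction], ...]
    products: tuple[tuple[Metabolite, Fraction], ...]
    reference: str
    solution_dim: int = 0

    def coefficient(self, name: str) -> Fraction:
        for met, c in self.substrates + self.products:
            if met.name == name:
                return c
        raise KeyError(name)

    def residuals(self) -> dict[str, Fraction]:
        return check_balance(self)

    def is_balanced(self) -> bool:
        return all(r == 0 for r in self.residuals().values())

    def integer_form(self, max_reference: int = 12) -> dict[str, int] | None:
        """All-integer scaling of the coefficients, if the scaled reference
        coefficient stays <= ``max_reference``; otherwise None."""
        denoms = [c.denominator for _, c in self.substrates + self.products]
        scale = lcm(*denoms) if denoms else 1
        ref = self.coefficient(self.reference) * scale
        if ref > max_reference:
            return None
        return {m.name: int(c * scale) for m, c in self.substrates + self.products}

    def as_dict(self) -> dict:
        return {
            "substrates": {m.name: [c.numerator, c.denominator] for m, c in self.substrates},
            "products": {m.name: [c.numerator, c.denominator] for m, c in self.products},
            "reference": self.reference,
            "solution_dim": self.solution_dim,
        }

    def __str__(self) -> str:
        def side(pairs):
            out = []
            for m, c in pairs:
                coeff = "" if c == 1 else f"{c} "
                out.append(f"{coeff}{m.name}")
            return " + ".join(out) if out else "(nothing)"

        return f"{side(self.substrates)} -> {side(self.products)}"


def check_balance(equation: BalancedEquation) -> dict[str, Fraction]:
    """Per-element residual: products minus substrates, weighted by
    coefficients. The zero map iff the equation is balanced."""
    res = {el: Fraction(0) for el in ELEMENTS}
    for met, c in equation.products:
        for el in ELEMENTS:
            res[el] += c * met.count(el)
    for met, c in equation.substrates:
        for el in ELEMENTS:
            res[el] -= c * met.count(el)
    return res


def _as_fraction(x) -> Fraction:
    r = sp.Rational(x)
    return Fraction(int(r.p), int(r.q))


def balance_equation(
    substrates: Sequence[Metabolite],
    products: Sequence[Metabolite],
    reference: str | Metabolite,
    fixed_ratios: Mapping[str, float | int | Fraction] | None = None,
) -> BalancedEquation:
    """Solve the elemental balance with the reference substrate fixed at 1.

    Parameters
    ----------
    substrates, products
        Species on each side; the reference must be among the substrates.
    reference
        Substrate whose coefficient is fixed to 1 (normalization).
    fixed_ratios
        Optional species -> coefficient constraints (e.g. one acetate
        co-consumed per fructoselysine) applied before solving.

    Returns the unique solution when the system is determined; for a
    one-dimensional family, the minimal non-negative all-integer member
    (smallest coefficient sum). Output is invariant under permutation of the
    input order (species are sorted internally).

    Raises
    ------
    BalanceInfeasibleError
        No non-negative solution exists; the violated elements are listed.
    BalanceAmbiguityError
        Solution space has dimension > 1, or dimension 1 with no
        non-negative integer member within bounds.
    """
    ref_name = reference.name if isinstance(reference, Metabolite) else reference
    subs = sorted(substrates, key=lambda m: m.name)
    prods = sorted(products, key=lambda m: m.name)
    if ref_name not in {m.name for m in subs}:
        raise ValueError(f"reference {ref_name!r} is not among the substrates")
    names = [m.name for m in subs] + [m.name for m in prods]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species in equation")

    fixed = {ref_name: Fraction(1)}
    for name, val in (fixed_ratios or {}).items():
        if name == ref_name:
            if Fraction(val) != 1:
                raise ValueError("reference coefficient is fixed at 1")
            continue
        if name not in names:
            raise ValueError(f"fixed ratio for unknown species {name!r}")
        fixed[name] = Fraction(val)

    species = list(subs) + list(prods)
    sign = {m.name: (-1 if i < len(subs) else +1) for i, m in enumerate(species)}
    free = [m for m in species if m.name not in fixed]

    # rows: elements actually present; columns: free species coefficients
    elements = [el for el in ELEMENTS if any(m.count(el) for m in species)]
    A = sp.zeros(len(elements), len(free))
    b = sp.zeros(len(elements), 1)
    for i, el in enumerate(elements):
        for j, m in enumerate(free):
            A[i, j] = sign[m.name] * m.count(el)
        rhs = 0
        for m in species:
            if m.name in fixed:
                rhs -= sign[m.name] * m.count(el) * sp.Rational(
                    fixed[m.name].numerator, fixed[m.name].denominator
                )
        b[i] = rhs

    try:
        sol, params = A.gauss_jordan_solve(b)
    except ValueError:
        violated = _violated_elements(A, b, elements)
        raise BalanceInfeasibleError(
            f"no elemental balance exists; inconsistent element(s): {', '.join(violated)}",
            violated_elements=violated,
        ) from None

    dim = len(params)
    if dim == 0:
        coeffs = {m.name: _as_fraction(sol[j]) for j, m in enumerate(free)}
    elif dim == 1:
        coeffs = _select_integer_member(sol, params[0], free)
    else:
        raise BalanceAmbiguityError(
            f"solution space has dimension {dim}; add fixed_ratios constraints",
            free_direction=None,
        )
    coeffs.update(fixed)

    negative = sorted(n for n, c in coeffs.items() if c < 0)
    if negative:
        raise BalanceInfeasibleError(
            "balance requires negative coefficients for: " + ", ".join(negative)
        )

    return BalancedEquation(
        substrates=tuple((m, coeffs[m.name]) for m in subs),
        products=tuple((m, coeffs[m.name]) for m in prods),
        reference=ref_name,
        solution_dim=dim,
    )


def _violated_elements(A, b, elements):
    """Elements whose balance rows make the system inconsistent."""
    aug = A.row_join(b)
    bad = []
    for i, el in enumerate(elements):
        rows = [k for k in range(A.rows) if k != i]
        sub_rank = A.extract(rows, list(range(A.cols))).rank()
        sub_aug_rank = aug.extract(rows, list(range(aug.cols))).rank()
        # dropping row i removes the inconsistency -> row i participates in it
        if A.rank() < aug.rank() and sub_rank == sub_aug_rank:
            bad.append(el)
    return bad or list(elements)


def _select_integer_member(sol, param, free):
    """Minimal non-negative all-integer member of a 1-D coefficient family.

    sol[j] = a_j + b_j * tau; enumerate tau values at which some coordinate
    hits an integer and keep candidates with every coordinate a non-negative
    integer <= MAX_INTEGER_COEFF; pick the smallest coefficient sum.
    """
    a = [sp.Rational(sp.expand(s).coeff(param, 0)) for s in sol]
    bvec = [sp.Rational(sp.expand(s).coeff(param, 1)) for s in sol]
    pivot = next((j for j, bj in enumerate(bvec) if bj != 0), None)
    if pivot is None:  # family is degenerate; constants only
        return {m.name: _as_fraction(a[j]) for j, m in enumerate(free)}

    candidates = []
    for n in range(0, MAX_INTEGER_COEFF + 1):
        tau = (sp.Integer(n) - a[pivot]) / bvec[pivot]
        coeffs = [a[j] + bvec[j] * tau for j in range(len(free))]
        if all(c.is_integer and 0 <= c <= MAX_INTEGER_COEFF for c in coeffs):
            candidates.append(coeffs)
    if not candidates:
        direction = {m.name: _as_fraction(bvec[j]) for j, m in enumerate(free)}
        raise BalanceAmbiguityError(
            "one-dimensional solution family has no non-negative integer member "
            f"with coefficients <= {MAX_INTEGER_COEFF}; free direction: {direction}",
            free_direction=direction,
        )
    best = min(candidates, key=lambda cs: (sum(cs), tuple(cs)))
    return {m.name: _as_fraction(best[j]) for j, m in enumerate(free)}
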