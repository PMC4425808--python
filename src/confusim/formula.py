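"""A small model-formula dialect for binomial mixed models.

Supported syntax::

    hit ~ log(n_items) * area * sigma + (1|subject_id)
    hit ~ poly(density, 2) * sigma + (1|subject_id)
    hit ~ factor(n_items) + poly(sigma, 2) + (1|subject_id)
    hit ~ 1 + (1|subject_id)

Atoms are ``name`` (numeric covariate), ``log(name)``, ``factor(name)``
(treatment-coded dummies, first sorted level as reference) and
``poly(name, 2)`` (degree-2 polynomial, orthogonal coding by default).
``a:b`` is an interaction; ``a*b`` expands to ``a + b + a:b`` (and
``a*b*c`` to all main effects and interactions).  Exactly one random term
``(1|group)`` — a per-group intercept — is required.  The intercept is
always included.

Orthogonal polynomial coding is computed from the data at matrix-build
time (QR of the centred Vandermonde, unit-norm columns, positive leading
sign); the fitted likelihood and BIC are invariant to the coding, raw
coding (x, x^2) is available for coefficient readability.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_RANDOM_RE = re.compile(r"\(\s*1\s*\|\s*([A-Za-z_]\w*)\s*\)")
_ATOM_RE = re.compile(
    r"^(?:(?P<func>log|factor)\(\s*(?P<var1>[A-Za-z_]\w*)\s*\)"
    r"|poly\(\s*(?P<var2>[A-Za-z_]\w*)\s*,\s*(?P<deg>\d+)\s*\)"
    r"|(?P<var3>[A-Za-z_]\w*))$"
)


@dataclass(frozen=True)
class Atom:
    """One covariate reference with a transform."""

    kind: str  # identity | log | factor | poly2
    var: str

    def label(self) -> str:
        if self.kind == "identity":
            return self.var
        if self.kind == "poly2":
            return f"poly({self.var},2)"
        return f"{self.kind}({self.var})"

    def expand(self, data: pd.DataFrame, raw_poly: bool) -> tuple[list[str], np.ndarray]:
        x = data[self.var].to_numpy()
        if self.kind == "identity":
            return [self.var], np.asarray(x, dtype=float)[:, None]
        if self.kind == "log":
            x = np.asarray(x, dtype=float)
            if np.any(x <= 0):
                raise ValueError(f"log({self.var}): non-positive values")
            return [f"log({self.var})"], np.log(x)[:, None]
        if self.kind == "factor":
            levels = np.unique(x)
            if len(levels) < 2:
                raise ValueError(f"factor({self.var}) has a single level")
            cols = [(x == lev).astype(float)[:, None] for lev in levels[1:]]
            names = [f"factor({self.var})[{lev}]" for lev in levels[1:]]
            return names, np.hstack(cols)
        if self.kind == "poly2":
            x = np.asarray(x, dtype=float)
            names = [f"poly({self.var},2)^{k}" for k in (1, 2)]
            if raw_poly:
                return names, np.column_stack([x, x**2])
            return names, _orthogonal_poly(x, 2)
        raise AssertionError(self.kind)


def _orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis of given degree, intercept removed."""
    if len(np.unique(x)) <= degree:
        raise ValueError("too few distinct values for the polynomial degree")
    xc = x - x.mean()
    vander = np.vander(xc, degree + 1, increasing=True)
    q, r = np.linalg.qr(vander)
    # fix sign convention so the linear column increases with x
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return q[:, 1:]


@dataclass(frozen=True)
class Term:
    """A fixed-effect term: a product of one or more atoms."""

    atoms: tuple

    def label(self) -> str:
        return ":".join(a.label() for a in self.atoms)

    def expand(self, data: pd.DataFrame, raw_poly: bool) -> tuple[list[str], np.ndarray]:
        names_parts, mats = zip(*(a.expand(data, raw_poly) for a in self.atoms))
        names, cols = [], []
        for combo in itertools.product(*(range(m.shape[1]) for m in mats)):
            names.append(":".join(np.array(p)[c] for p, c in zip(names_parts, combo)))
            col = mats[0][:, combo[0]].copy()
            for m, c in zip(mats[1:], combo[1:]):
                col *= m[:, c]
            cols.append(col[:, None])
        return names, np.hstack(cols)


@dataclass(frozen=True)
class ModelSpec:
    """Parsed model: response, fixed-effect terms, grouping factor."""

    response: str
    terms: tuple
    group: str
    formula: str = ""
    raw_poly: bool = False

    @property
    def link(self) -> str:
        return "logit"

    @property
    def family(self) -> str:
        return "binomial"

    def with_raw_poly(self) -> "ModelSpec":
        return ModelSpec(self.response, self.terms, self.group, self.formula, True)


def _parse_atom(text: str) -> Atom | None:
    m = _ATOM_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse term atom {text!r}")
    if m.group("func"):
        return Atom(m.group("func"), m.group("var1"))
    if m.group("var2"):
        if int(m.group("deg")) != 2:
            raise ValueError("only poly(x, 2) is supported")
        return Atom("poly2", m.group("var2"))
    var = m.group("var3")
    if var == "1":  # pragma: no cover - intercept handled before this point
        return None
    return Atom("identity", var)


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` outside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return [p.strip() for p in parts if p.strip()]


def parse_formula(formula: str, raw_poly: bool = False) -> ModelSpec:
    """Parse a formula string into a :class:`ModelSpec`."""
    if "~" not in formula:
        raise ValueError("formula must contain '~'")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    if not re.match(r"^[A-Za-z_]\w*$", response):
        raise ValueError(f"bad response name {response!r}")

    groups = _RANDOM_RE.findall(rhs)
    if len(groups) != 1:
        raise ValueError("exactly one random term (1|group) is required")
    group = groups[0]
    rhs = _RANDOM_RE.sub("", rhs)

    terms: list[Term] = []
    seen = set()

    def add(term: Term) -> None:
        if term.label() not in seen:
            seen.add(term.label())
            terms.append(term)

    for chunk in _split_top(rhs, "+"):
        if chunk == "1":
            continue
        star_parts = _split_top(chunk, "*")
        if len(star_parts) > 1:
            atoms = [_must_atom(p) for p in star_parts]
            for r in range(1, len(atoms) + 1):
                for combo in itertools.combinations(atoms, r):
                    add(Term(tuple(combo)))
        else:
            colon_parts = _split_top(chunk, ":")
            add(Term(tuple(_must_atom(p) for p in colon_parts)))

    # main effects before interactions, stable within order
    terms.sort(key=lambda t: len(t.atoms))
    return ModelSpec(response, tuple(terms), group, formula.strip(), raw_poly)


def _must_atom(text: str) -> Atom:
    atom = _parse_atom(text)
    if atom is None:
        raise ValueError(f"'1' cannot appear inside an interaction: {text!r}")
    return atom


def build_matrices(spec: ModelSpec, data: pd.DataFrame):
    """Design matrix, response, and group codes, sorted by group.

    Returns ``(X, names, y, group_codes, group_levels, order)`` where
    ``order`` is the row permutation applied (stable sort by group) so
    callers can map back to the input row order.
    """
    for col in [spec.response, spec.group]:
        if col not in data.columns:
            raise ValueError(f"data lacks column {col!r}")
    order = np.argsort(data[spec.group].to_numpy(), kind="stable")
    data = data.iloc[order].reset_index(drop=True)

    y = data[spec.response].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("response must be binary 0/1")
    group_levels, group_codes = np.unique(data[spec.group].to_numpy(), return_inverse=True)

    names = ["(Intercept)"]
    cols = [np.ones((len(data), 1))]
    for term in spec.terms:
        n, m = term.expand(data, spec.raw_poly)
        names.extend(n)
        cols.append(m)
    X = np.hstack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design matrix")
    return X, names, y, group_codes, group_levels, order
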