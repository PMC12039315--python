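"""SEM model specification: path-syntax parsing and RAM parameterization.

Grammar (one statement per line, ``#`` comments):

    F =~ a + b + c      measurement: F loads on indicators a, b, c
    y ~ x1 + x2         regression of y on x1 and x2
    a ~~ b              covariance (variance when a == b)

A numeric prefix fixes a parameter (``0.5*b``); an alphabetic prefix labels
it (``lab*b``), and identical labels impose an equality constraint.

The model-implied covariance follows the RAM parameterization
Σ = F (I-A)⁻¹ S₀ (I-A)⁻ᵀ Fᵀ, with A holding directed coefficients
(loadings, regressions), S₀ undirected (co)variances and F selecting the
observed rows.

Identification conventions:

``unit_variance`` (default) — exogenous latent variances fixed to 1, all
loadings free.  ``unit_loading`` — first loading of each latent fixed to 1,
latent variance free.

When a model is fitted to a genetic *correlation* matrix, every free
variance (residual or latent disturbance) is profiled out: it is derived so
that the implied total variance of its variable is exactly 1, mirroring the
unit-diagonal data.  Profiled variances are reported as estimates but are
not optimized parameters; degrees of freedom are computed against the
off-diagonal moments only, which is arithmetically identical to counting
all unique moments against all free parameters including variances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Parameter", "ModelSpec", "parse_model", "implied_sigma"]

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


@dataclass(frozen=True)
class Parameter:
    """One path-model parameter (an entry of A or S₀)."""

    op: str                 # '=~', '~', '~~'
    lhs: str
    rhs: str
    free: bool = True
    value: float | None = None   # fixed value, or None for free
    label: str | None = None

    @property
    def name(self) -> str:
        return f"{self.lhs} {self.op} {self.rhs}"


@dataclass
class ModelSpec:
    """Parsed model: parameters plus variable bookkeeping."""

    parameters: list[Parameter]
    latents: list[str]
    observed: list[str]
    identification: str = "unit_variance"

    def variables(self) -> list[str]:
        return self.observed + self.latents

    def free_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters if p.free]

    def parameter_classes(self) -> list[list[int]]:
        """Indices of free parameters grouped into equality classes.

        Unlabeled free parameters form singleton classes; parameters
        sharing a label share one class (the spec-level device for
        equality-constrained model comparisons).
        """
        classes: dict[str, list[int]] = {}
        order: list[str] = []
        for i, p in enumerate(self.parameters):
            if not p.free:
                continue
            key = p.label if p.label is not None else f"__{i}"
            if key not in classes:
                classes[key] = []
                order.append(key)
            classes[key].append(i)
        return [classes[k] for k in order]

    def n_free(self) -> int:
        """Free parameter count after equality collapsing (incl. variances)."""
        return len(self.parameter_classes())

    def endogenous(self) -> set[str]:
        """Variables that receive a directed arrow."""
        out = set()
        for p in self.parameters:
            if p.op == "~":
                out.add(p.lhs)
            elif p.op == "=~":
                out.add(p.rhs)
        return out

    def with_equality(self, pairs: list[tuple[str, str]], label: str) -> "ModelSpec":
        """Return a copy in which the covariances named by ``pairs``
        (unordered variable pairs) share one equality label."""
        params = []
        hit = 0
        targets = {frozenset(p) for p in pairs}
        for p in self.parameters:
            if p.op == "~~" and frozenset((p.lhs, p.rhs)) in targets:
                params.append(replace(p, label=label))
                hit += 1
            else:
                params.append(p)
        if hit != len(pairs):
            raise ValueError(
                f"equality constraint matched {hit} of {len(pairs)} covariances"
            )
        return ModelSpec(params, list(self.latents), list(self.observed),
                         self.identification)


def _parse_term(term: str, line_no: int) -> tuple[str, bool, float | None, str | None]:
    term = term.strip()
    if "*" in term:
        prefix, _, var = term.partition("*")
        prefix, var = prefix.strip(), var.strip()
        if not _NAME_RE.match(var):
            raise ValueError(f"line {line_no}: bad variable name {var!r}")
        if _NUM_RE.match(prefix):
            return var, False, float(prefix), None
        if not _NAME_RE.match(prefix):
            raise ValueError(f"line {line_no}: bad modifier {prefix!r}")
        return var, True, None, prefix
    if not _NAME_RE.match(term):
        raise ValueError(f"line {line_no}: bad variable name {term!r}")
    return term, True, None, None


def parse_model(text: str, identification: str = "unit_variance") -> ModelSpec:
    """Parse path-syntax text into a :class:`ModelSpec`.

    Variances are auto-completed: every referenced variable without an
    explicit variance statement receives one (free, or fixed to 1 for
    exogenous latents under ``unit_variance``).  Under ``unit_loading`` the
    first listed indicator of each latent has its loading fixed to 1.
    """
    if identification not in ("unit_variance", "unit_loading"):
        raise ValueError(f"unknown identification convention {identification!r}")
    if not text.strip():
        raise ValueError("empty model specification")
    raw: list[tuple[int, str, str, str, bool, float | None, str | None]] = []
    latents: list[str] = []
    seen_vars: list[str] = []

    def note(v):
        if v not in seen_vars:
            seen_vars.append(v)

    for line_no, line in enumerate(text.splitlines(), start=1):
        stmt = line.split("#", 1)[0].strip()
        if not stmt:
            continue
        for op in ("=~", "~~", "~"):
            if op in stmt:
                lhs_s, _, rhs_s = stmt.partition(op)
                break
        else:
            raise ValueError(f"line {line_no}: no operator in {stmt!r}")
        lhs = lhs_s.strip()
        lhs_label = None
        lhs_fixed = None
        if "*" in lhs:  # modifier on the left (applies to the whole statement)
            lhs, _, fixed, lhs_label = _parse_term(lhs, line_no)
            lhs_fixed = fixed
        if not _NAME_RE.match(lhs):
            raise ValueError(f"line {line_no}: bad variable name {lhs!r}")
        note(lhs)
        if op == "=~" and lhs not in latents:
            latents.append(lhs)
        terms = [t for t in rhs_s.split("+")]
        if not terms or not rhs_s.strip():
            raise ValueError(f"line {line_no}: empty right-hand side")
        for pos, term in enumerate(terms):
            var, free, value, label = _parse_term(term, line_no)
            if lhs_label is not None and label is None:
                label = lhs_label
            if lhs_fixed is not None and value is None:
                free, value = False, lhs_fixed
            note(var)
            raw.append((line_no, op, lhs, var, free, value, label))

    observed = [v for v in seen_vars if v not in latents]

    # deduplicate, catching inconsistent double fixing
    entries: dict[tuple[str, str, str], tuple[int, bool, float | None, str | None]] = {}
    order: list[tuple[str, str, str]] = []
    for line_no, op, lhs, rhs, free, value, label in raw:
        a, b = lhs, rhs
        if op == "~~" and observed_index(observed, latents, a) > observed_index(observed, latents, b):
            a, b = b, a  # canonical unordered pair
        key = (op, a, b)
        if key in entries:
            _, pfree, pvalue, plabel = entries[key]
            if (pfree != free) or (pvalue is not None and value is not None and pvalue != value):
                raise ValueError(
                    f"line {line_no}: parameter {a} {op} {b} declared twice "
                    f"with inconsistent fixing"
                )
            if label is not None and plabel is None:
                entries[key] = (line_no, free, value, label)
            continue
        entries[key] = (line_no, free, value, label)
        order.append(key)

    params: list[Parameter] = []
    first_loading_seen: set[str] = set()
    for key in order:
        op, lhs, rhs = key
        _, free, value, label = entries[key]
        if (op == "=~" and identification == "unit_loading"
                and lhs not in first_loading_seen):
            first_loading_seen.add(lhs)
            if free and value is None and label is None:
                free, value = False, 1.0
        params.append(Parameter(op, lhs, rhs, free, value, label))

    # auto-complete variances
    have_var = {p.lhs for p in params if p.op == "~~" and p.lhs == p.rhs}
    endo = ModelSpec(params, latents, observed, identification).endogenous()
    for v in observed + latents:
        if v in have_var:
            continue
        if (v in latents and identification == "unit_variance" and v not in endo):
            params.append(Parameter("~~", v, v, False, 1.0, None))
        else:
            params.append(Parameter("~~", v, v, True, None, None))

    return ModelSpec(params, latents, observed, identification)


def observed_index(observed: list[str], latents: list[str], v: str) -> int:
    allv = observed + latents
    return allv.index(v) if v in allv else len(allv)


# ---------------------------------------------------------------------------
# RAM machinery


class RAMModel:
    """Compiled form of a ModelSpec against a fixed observed-variable order.

    Exposes sigma(theta): the model-implied covariance among the observed
    variables, with free variances profiled to the unit diagonal when
    ``profile_variances`` is on (correlation-metric fitting).
    """

    def __init__(self, spec: ModelSpec, observed_order: list[str],
                 profile_variances: bool = True):
        missing = [v for v in spec.observed if v not in observed_order]
        if missing:
            raise ValueError(f"model references unknown variables: {missing}")
        self.spec = spec
        self.observed = [v for v in observed_order if v in spec.observed]
        self.var_names = self.observed + spec.latents
        self.n_all = len(self.var_names)
        self.n_obs = len(self.observed)
        self.vidx = {v: i for i, v in enumerate(self.var_names)}
        self.classes = spec.parameter_classes()
        self.n_theta_raw = len(self.classes)

        # slot assignments: (matrix, i, j) per parameter index
        self.slots: list[tuple[str, int, int]] = []
        for p in spec.parameters:
            if p.op == "=~":
                self.slots.append(("A", self.vidx[p.rhs], self.vidx[p.lhs]))
            elif p.op == "~":
                self.slots.append(("A", self.vidx[p.lhs], self.vidx[p.rhs]))
            else:
                self.slots.append(("S", self.vidx[p.lhs], self.vidx[p.rhs]))

        endo = spec.endogenous()
        self.profiled: list[int] = []   # parameter indices whose variance is derived
        profiled_classes: set[int] = set()
        if profile_variances:
            for ci, members in enumerate(self.classes):
                p = spec.parameters[members[0]]
                if p.op == "~~" and p.lhs == p.rhs and p.label is None:
                    v = p.lhs
                    if v in spec.observed or (
                        spec.identification == "unit_variance"
                    ):
                        profiled_classes.add(ci)
                        self.profiled.extend(members)
        self.theta_classes = [c for i, c in enumerate(self.classes)
                              if i not in profiled_classes]
        self.theta_names = [spec.parameters[c[0]].label
                            or spec.parameters[c[0]].name
                            for c in self.theta_classes]
        self.n_theta = len(self.theta_classes)
        self.n_profiled = len(profiled_classes)
        self._build_depths()

    # -- profiled-variance derivation order ---------------------------------
    def _build_depths(self) -> None:
        n = self.n_all
        adj = [[] for _ in range(n)]  # parent -> child along directed arrows
        for p in self.spec.parameters:
            if p.op == "=~":
                adj[self.vidx[p.lhs]].append(self.vidx[p.rhs])
            elif p.op == "~":
                adj[self.vidx[p.rhs]].append(self.vidx[p.lhs])
        depth = [0] * n
        for _ in range(n + 1):
            changed = False
            for u in range(n):
                for v in adj[u]:
                    if depth[v] < depth[u] + 1:
                        depth[v] = depth[u] + 1
                        changed = True
            if not changed:
                break
        else:
            raise ValueError("cyclic model: directed paths form a loop")
        prof_vars = sorted(
            {self.vidx[self.spec.parameters[i].lhs] for i in self.profiled}
        )
        levels: dict[int, list[int]] = {}
        for v in prof_vars:
            levels.setdefault(depth[v], []).append(v)
        self.profiled_levels = [levels[d] for d in sorted(levels)]
        self.profiled_vars = prof_vars

    # -- evaluation ----------------------------------------------------------
    def _fill(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_all
        A = np.zeros((n, n))
        S0 = np.zeros((n, n))
        values = np.empty(len(self.spec.parameters))
        values.fill(np.nan)
        for p_idx, p in enumerate(self.spec.parameters):
            if not p.free:
                values[p_idx] = p.value
        for t, members in enumerate(self.theta_classes):
            for m in members:
                values[m] = theta[t]
        for m in self.profiled:
            values[m] = 0.0  # derived below
        for p_idx, (mat, i, j) in enumerate(self.slots):
            val = values[p_idx]
            if mat == "A":
                A[i, j] = val
            else:
                S0[i, j] = val
                S0[j, i] = val
        return A, S0

    def sigma_full(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Σ_observed, S₀ with derived variances, total covariance T)."""
        A, S0 = self._fill(theta)
        eye = np.eye(self.n_all)
        try:
            B = np.linalg.inv(eye - A)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular (I - A): cyclic or ill-specified model") from err
        for level in self.profiled_levels:
            T = B @ S0 @ B.T
            for v in level:
                S0[v, v] = S0[v, v] + (1.0 - T[v, v])
        T = B @ S0 @ B.T
        return T[: self.n_obs, : self.n_obs], S0, T

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        return self.sigma_full(theta)[0]

    def start_values(self, S: np.ndarray | None = None) -> np.ndarray:
        """Loadings 0.5, regressions/covariances 0, variances from diag(S)."""
        theta = np.zeros(self.n_theta)
        for t, members in enumerate(self.theta_classes):
            p = self.spec.parameters[members[0]]
            if p.op == "=~":
                theta[t] = 0.5
            elif p.op == "~~" and p.lhs == p.rhs:
                if S is not None and p.lhs in self.observed:
                    i = self.observed.index(p.lhs)
                    theta[t] = 0.5 * S[i, i]
                else:
                    theta[t] = 0.5
        return theta


def implied_sigma(spec: ModelSpec, theta: np.ndarray,
                  observed_order: list[str] | None = None,
                  profile_variances: bool = False) -> np.ndarray:
    """Model-implied covariance among the observed variables.

    ``theta`` is ordered as the model's free-parameter equality classes
    (declaration order); by default no variances are profiled, so theta
    covers every free parameter including variances.
    """
    ram = RAMModel(spec, observed_order or spec.observed, profile_variances)
    if len(theta) != ram.n_theta:
        raise ValueError(f"theta must have length {ram.n_theta}, got {len(theta)}")
    return ram.sigma(np.asarray(theta, dtype=float))
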