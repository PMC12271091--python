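"""Structural equation model specification and implied covariance.

Models are declared in a compact text syntax::

    F =~ a + b + c          # factor loadings
    x ~~ y                  # (co)variance
    y ~ x1 + x2             # regression
    U ~~ 0*C                # fixed constant (here: orthogonality)
    F =~ NA*a + b           # NA* frees a parameter that would be fixed

Internally the model is held in RAM form over the stacked variable set
(observed then latent): an asymmetric matrix A of loadings/regressions, a
symmetric matrix P of variances/covariances, and the filter selecting the
observed rows.  The implied covariance is

    Sigma = F (I - A)^-1 P (I - A)^-T F^T

which reproduces Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta for
measurement/structural partitions, with single-indicator observed
variables carried directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Parameter", "ModelSpec", "ModelSyntaxError", "parse_model", "implied_cov"]


class ModelSyntaxError(ValueError):
    pass


@dataclass
class Parameter:
    """One entry of the parameter table.

    ``matrix`` is "A" (lhs <- rhs: loading or regression path) or "P"
    (symmetric lhs ~~ rhs).  Free parameters carry a start value; fixed
    ones a constant.
    """

    lhs: str
    rhs: str
    matrix: str
    free: bool
    value: float  # start value if free, constant otherwise
    name: str = ""
    kind: str = ""  # "loading", "reg" or "cov"; for serialization only

    def label(self) -> str:
        op = "~" if self.matrix == "A" else "~~"
        return f"{self.lhs}{op}{self.rhs}"


@dataclass
class ModelSpec:
    """Symbolic latent-variable model over named variables.

    Two table entries sharing one ``name`` denote an equality constraint:
    they are a single free parameter.
    """

    observed: list[str]
    latents: list[str]
    params: list[Parameter] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return self.observed + self.latents

    def free_params(self) -> list[Parameter]:
        """First table entry for each unique free parameter name."""
        seen: dict[str, Parameter] = {}
        for p in self.params:
            if p.free and p.name not in seen:
                seen[p.name] = p
        return list(seen.values())

    @property
    def n_free(self) -> int:
        return len(self.free_params())

    @property
    def n_moments(self) -> int:
        k = len(self.observed)
        return k * (k + 1) // 2

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    def start_vector(self) -> np.ndarray:
        return np.array([p.value for p in self.free_params()])

    def param_names(self) -> list[str]:
        return [p.name for p in self.free_params()]

    def serialize(self) -> str:
        """Model text that parses back to an identical parameter table."""
        lines = []
        for p in self.params:
            if p.free:
                default = (f"{p.rhs}=~{p.lhs}" if p.kind == "loading"
                           else f"{p.lhs}~{p.rhs}" if p.matrix == "A"
                           else f"{p.lhs}~~{p.rhs}")
                pre = "NA*" if p.name == default else f"{p.name}*"
            else:
                pre = f"{p.value:g}*"
            if p.kind == "loading":
                lines.append(f"{p.rhs} =~ {pre}{p.lhs}")
            elif p.matrix == "A":
                lines.append(f"{p.lhs} ~ {pre}{p.rhs}")
            else:
                lines.append(f"{p.lhs} ~~ {pre}{p.rhs}")
        return "\n".join(lines)

    # -- RAM assembly -------------------------------------------------------

    def _index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    def ram_matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Populate (A, P) at parameter vector theta."""
        nv = len(self.variables)
        idx = self._index()
        a = np.zeros((nv, nv))
        p_mat = np.zeros((nv, nv))
        by_name = dict(zip(self.param_names(), np.asarray(theta, float)))
        for par in self.params:
            val = by_name[par.name] if par.free else par.value
            i, j = idx[par.lhs], idx[par.rhs]
            if par.matrix == "A":
                a[i, j] = val
            else:
                p_mat[i, j] = val
                p_mat[j, i] = val
        return a, p_mat


def implied_cov(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance matrix of the observed variables."""
    theta = np.asarray(theta, float)
    if len(theta) != spec.n_free:
        raise ValueError(f"theta has {len(theta)} entries, expected {spec.n_free}")
    a, p_mat = spec.ram_matrices(theta)
    nv = a.shape[0]
    eye = np.eye(nv)
    try:
        inv = np.linalg.solve(eye - a, eye)
    except np.linalg.LinAlgError as exc:
        raise ValueError("(I - A) singular: cyclic regression structure") from exc
    total = inv @ p_mat @ inv.T
    k = len(spec.observed)
    sigma = total[:k, :k]
    return (sigma + sigma.T) / 2


def total_cov(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Implied covariance of ALL variables (observed + latent)."""
    a, p_mat = spec.ram_matrices(np.asarray(theta, float))
    nv = a.shape[0]
    inv = np.linalg.solve(np.eye(nv) - a, np.eye(nv))
    t = inv @ p_mat @ inv.T
    return (t + t.T) / 2


# ---------------------------------------------------------------------------
# parser

_MOD_RE = re.compile(r"^([^*]+)\*(.+)$")
_NUM_RE = re.compile(r"^[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?$")


def _split_terms(text: str) -> list[tuple[str, bool, float, str | None]]:
    """Parse 'a + 0.5*b + NA*c + lab*d' into (variable, free, value, label).

    A numeric modifier fixes the parameter; ``NA*`` forces it free; any
    other identifier is a label, and terms sharing a label share a single
    free parameter (equality constraint).
    """
    out = []
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ModelSyntaxError(f"empty term in {text!r}")
        m = _MOD_RE.match(term)
        if m:
            mod, name = m.group(1).strip(), m.group(2).strip()
            if mod == "NA":
                out.append((name, True, np.nan, None))
            elif _NUM_RE.match(mod):
                out.append((name, False, float(mod), None))
            elif re.fullmatch(r"[A-Za-z_]\w*", mod):
                out.append((name, True, np.nan, mod))
            else:
                raise ModelSyntaxError(f"bad modifier {mod!r} in {term!r}")
        else:
            out.append((term, True, np.nan, None))
    return out


def parse_model(
    text: str,
    identification: str = "unit_variance",
    default_loading_start: float = 0.5,
    allowed_vars: list[str] | None = None,
) -> ModelSpec:
    """Parse model syntax into a :class:`ModelSpec` with defaults applied.

    Defaults: every observed variable gets a free residual variance (start
    0.05) unless declared; latent variances are fixed at 1 under
    ``unit_variance`` identification, or the first loading is fixed at 1
    under ``marker_loading`` (latent variance then free).

    When ``allowed_vars`` is given (e.g. the trait labels of the matrices
    the model will be fitted to), any observed variable outside it is a
    parse error.
    """
    if identification not in ("unit_variance", "marker_loading"):
        raise ValueError(f"unknown identification {identification!r}")
    if not text.strip():
        raise ModelSyntaxError("empty model text")

    # each entry: (lhs/latent, variable, free, value, label)
    loadings: list[tuple[str, str, bool, float, str | None]] = []
    covs: list[tuple[str, str, bool, float, str | None]] = []
    regs: list[tuple[str, str, bool, float, str | None]] = []
    latents: list[str] = []
    mentioned: list[str] = []

    def _note(v: str) -> None:
        if v not in mentioned:
            mentioned.append(v)

    for ln, rawline in enumerate(text.splitlines(), 1):
        line = rawline.split("#")[0].strip()
        if not line:
            continue
        for op, bucket in (("=~", "load"), ("~~", "cov"), ("~", "reg")):
            if op in line:
                lhs, rhs = (s.strip() for s in line.split(op, 1))
                if not lhs or not rhs:
                    raise ModelSyntaxError(f"line {ln}: malformed {op!r} statement")
                if not re.fullmatch(r"[A-Za-z_][\w.\-]*", lhs):
                    raise ModelSyntaxError(f"line {ln}: bad variable name {lhs!r}")
                terms = _split_terms(rhs)
                if bucket == "load":
                    if lhs not in latents:
                        latents.append(lhs)
                    for name, fr, val, lab in terms:
                        loadings.append((lhs, name, fr, val, lab))
                        _note(name)
                elif bucket == "cov":
                    for name, fr, val, lab in terms:
                        covs.append((lhs, name, fr, val, lab))
                        _note(lhs)
                        _note(name)
                else:
                    _note(lhs)
                    for name, fr, val, lab in terms:
                        regs.append((lhs, name, fr, val, lab))
                        _note(name)
                break
        else:
            raise ModelSyntaxError(f"line {ln}: no operator (=~, ~~, ~) found")

    observed = [v for v in mentioned if v not in latents]
    if allowed_vars is not None:
        bad = [v for v in observed if v not in allowed_vars]
        if bad:
            raise ModelSyntaxError(f"reference to unknown variable(s) {bad}")
    known = set(observed) | set(latents)
    for _, name, _, _, _ in loadings:
        if name not in known:  # pragma: no cover - loadings define their targets
            raise ModelSyntaxError(f"unknown variable {name!r}")
    for lhs, rhs, _, _, _ in covs + regs:
        for v in (lhs, rhs):
            if v not in known:
                raise ModelSyntaxError(f"reference to unknown variable {v!r}")

    # under-identification guard: a latent with a single indicator and no
    # fixed loading cannot be separated from that indicator's residual
    for lat in latents:
        inds = [(o, fr, val) for la, o, fr, val, _ in loadings if la == lat]
        if len(inds) < 2 and all(fr for _, fr, _ in inds):
            raise ModelSyntaxError(
                f"latent {lat!r} has <2 indicators and no fixed loading"
            )

    params: list[Parameter] = []
    declared_cov = {(min(l, r), max(l, r)) for l, r, _, _, _ in covs}

    for lat, obs_v, fr, val, lab in loadings:
        if identification == "marker_loading" and fr and lab is None:
            first = next(o for la, o, _, _, _ in loadings if la == lat)
            if obs_v == first:
                fr, val = False, 1.0
        start = default_loading_start if fr and np.isnan(val) else val
        params.append(Parameter(obs_v, lat, "A", fr, start,
                                name=lab or f"{lat}=~{obs_v}", kind="loading"))
    for lhs, rhs, fr, val, lab in regs:
        start = 0.0 if fr and np.isnan(val) else val
        params.append(Parameter(lhs, rhs, "A", fr, start,
                                name=lab or f"{lhs}~{rhs}", kind="reg"))
    for lhs, rhs, fr, val, lab in covs:
        start = (0.05 if lhs == rhs else 0.0) if fr and np.isnan(val) else val
        params.append(Parameter(lhs, rhs, "P", fr, start,
                                name=lab or f"{lhs}~~{rhs}", kind="cov"))

    # default variances
    reg_outcomes = {lhs for lhs, _, _, _, _ in regs}
    for lat in latents:
        if (lat, lat) not in declared_cov:
            if identification == "unit_variance" and lat not in reg_outcomes:
                params.append(Parameter(lat, lat, "P", False, 1.0,
                                        name=f"{lat}~~{lat}"))
            else:
                params.append(Parameter(lat, lat, "P", True, 1.0,
                                        name=f"{lat}~~{lat}"))
    indicator_set = {o for _, o, _, _, _ in loadings}
    for v in observed:
        if (v, v) not in declared_cov:
            start = 0.05 if v in indicator_set else 0.1
            params.append(Parameter(v, v, "P", True, start, name=f"{v}~~{v}"))

    return ModelSpec(observed=observed, latents=latents, params=params)
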