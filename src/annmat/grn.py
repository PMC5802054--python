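"""Single-cell simulation from boolean gene-regulatory networks.

Each gene carries a boolean update rule (AND/OR/NOT over genes).  The rules
are relaxed to a continuous homologue: a literal becomes a normalized Hill
function h(x) = x^n/(x^n + k^n) · (1 + k^n) (so h(0)=0, h(1)=1), NOT is
1 − h, AND is the product, and OR the probabilistic sum 1 − (1−u)(1−v).  Cell
states evolve by the Euler–Maruyama discretization

    x ← clamp(x + τ·(B(x) − x) + √τ·σ·η,  0, 1),

with B the per-gene rule homologue and η standard normal.  Snapshot sampling
of independent noisy trajectories at uniformly drawn times yields synthetic
single-cell expression matrices whose attractor structure mirrors the
network's boolean attractors.

Model text format: one line per gene, ``gene = expression``; ``#`` starts a
comment; operators ``AND``, ``OR``, ``NOT`` and parentheses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .core import AnnMatrix


class ModelError(ValueError):
    """Malformed boolean network model."""


# -- boolean expression AST ----------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|AND\b|OR\b|NOT\b|[A-Za-z_][\w.\-]*)", re.IGNORECASE)


def _tokenize(text: str) -> list[str]:
    pos, out = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ModelError(f"cannot tokenize rule near {text[pos:]!r}")
            break
        tok = m.group(1)
        out.append(tok.upper() if tok.upper() in ("AND", "OR", "NOT") else tok)
        pos = m.end()
    return out


class _Parser:
    """Recursive descent: expr := term (OR term)*; term := factor (AND factor)*;
    factor := NOT factor | '(' expr ')' | gene."""

    def __init__(self, tokens: list[str], genes: dict[str, int]):
        self.tokens = tokens
        self.genes = genes
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def eat(self, tok=None):
        cur = self.peek()
        if cur is None or (tok is not None and cur != tok):
            raise ModelError(f"expected {tok or 'token'}, got {cur!r}")
        self.pos += 1
        return cur

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise ModelError(f"trailing tokens in rule: {self.tokens[self.pos:]}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "OR":
            self.eat("OR")
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "AND":
            self.eat("AND")
            node = ("and", node, self.factor())
        return node

    def factor(self):
        tok = self.peek()
        if tok == "NOT":
            self.eat("NOT")
            return ("not", self.factor())
        if tok == "(":
            self.eat("(")
            node = self.expr()
            self.eat(")")
            return node
        name = self.eat()
        if name in ("AND", "OR", ")"):
            raise ModelError(f"unexpected token {name!r} in rule")
        if name not in self.genes:
            raise ModelError(f"unknown gene {name!r} referenced in rule")
        return ("lit", self.genes[name])


def parse_rule(rule: str, genes: dict[str, int]):
    """Parse a boolean expression over the declared genes into an AST."""
    tokens = _tokenize(rule)
    if not tokens:
        raise ModelError("empty rule")
    return _Parser(tokens, genes).parse()


@dataclass
class GRNModel:
    """Boolean network with Hill-transform and integration parameters.

    ``rules`` maps gene name → boolean expression string.  ``hill_n`` ≥ 1 is
    the Hill exponent, ``hill_k`` ∈ (0, 1) the half-activation threshold,
    ``dt`` the Euler step τ, ``noise_sd`` the σ of the additive Gaussian noise.
    """

    genes: list[str]
    rules: dict[str, str]
    hill_n: float = 2.0
    hill_k: float = 0.5
    dt: float = 0.01
    noise_sd: float = 0.01
    seed: int = 0
    _asts: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.hill_n < 1:
            raise ModelError(f"hill_n must be ≥ 1, got {self.hill_n}")
        if not 0 < self.hill_k < 1:
            raise ModelError(f"hill_k must be in (0, 1), got {self.hill_k}")
        if self.dt <= 0:
            raise ModelError(f"dt must be positive, got {self.dt}")
        if self.noise_sd < 0:
            raise ModelError(f"noise_sd must be ≥ 0, got {self.noise_sd}")
        index = {g: i for i, g in enumerate(self.genes)}
        if len(index) != len(self.genes):
            raise ModelError("duplicate gene names")
        missing = [g for g in self.genes if g not in self.rules]
        if missing:
            raise ModelError(f"genes without a rule: {missing}")
        self._asts = [parse_rule(self.rules[g], index) for g in self.genes]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    # -- continuous homologue --------------------------------------------------

    def _hill(self, x: np.ndarray) -> np.ndarray:
        n, k = self.hill_n, self.hill_k
        xn = np.power(np.clip(x, 0.0, 1.0), n)
        return xn / (xn + k**n) * (1.0 + k**n)

    def _eval(self, node, x: np.ndarray) -> np.ndarray:
        op = node[0]
        if op == "lit":
            return np.clip(self._hill(x[..., node[1]]), 0.0, 1.0)
        if op == "not":
            return 1.0 - self._eval(node[1], x)
        if op == "and":
            return self._eval(node[1], x) * self._eval(node[2], x)
        if op == "or":
            u, v = self._eval(node[1], x), self._eval(node[2], x)
            return 1.0 - (1.0 - u) * (1.0 - v)
        raise ModelError(f"unknown AST node {op!r}")

    def rule_homologue(self, gene: str, x) -> float | np.ndarray:
        """Evaluate one gene's continuous rule at state(s) ``x`` ∈ [0,1]^G."""
        x = np.asarray(x, dtype=np.float64)
        return self._eval(self._asts[self.genes.index(gene)], x)

    def drift_target(self, x: np.ndarray) -> np.ndarray:
        """B(x): stacked rule homologues; the ODE is dx/dt = B(x) − x."""
        x = np.asarray(x, dtype=np.float64)
        return np.stack([self._eval(ast, x) for ast in self._asts], axis=-1)

    # -- integration -------------------------------------------------------------

    def simulate_trajectory(
        self, x0, n_steps: int, seed: int | None = None
    ) -> np.ndarray:
        """Euler–Maruyama path of length ``n_steps`` (initial state excluded)."""
        x = np.asarray(x0, dtype=np.float64)
        if x.shape != (self.n_genes,):
            raise ValueError(f"x0 must have shape ({self.n_genes},), got {x.shape}")
        if (x < 0).any() or (x > 1).any():
            raise ValueError("x0 must lie in [0, 1]^G")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        out = np.empty((n_steps, self.n_genes))
        sqrt_dt = np.sqrt(self.dt)
        for t in range(n_steps):
            drift = self.drift_target(x) - x
            x = x + self.dt * drift
            if self.noise_sd > 0:
                x = x + sqrt_dt * self.noise_sd * rng.standard_normal(self.n_genes)
            np.clip(x, 0.0, 1.0, out=x)
            out[t] = x
        return out

    def sample_cells(
        self, x0, n_cells: int, n_steps: int, seed: int | None = None
    ) -> AnnMatrix:
        """Snapshot sampling: each cell is one independent noisy trajectory
        observed at a uniformly drawn step in [1, n_steps]."""
        if n_cells < 1:
            raise ValueError(f"n_cells must be ≥ 1, got {n_cells}")
        base = self.seed if seed is None else seed
        rng = np.random.default_rng(base)
        times = rng.integers(1, n_steps + 1, size=n_cells)
        X = np.empty((n_cells, self.n_genes))
        for c in range(n_cells):
            traj = self.simulate_trajectory(x0, int(times[c]), seed=base + 1 + c)
            X[c] = traj[-1]
        return AnnMatrix(
            X,
            obs_names=[f"cell{c}" for c in range(n_cells)],
            var_names=list(self.genes),
            obs={
                "sim_time": times.astype(np.int64),
                "trajectory_id": np.arange(n_cells, dtype=np.int64),
            },
            uns={"grn_params": {
                "hill_n": self.hill_n, "hill_k": self.hill_k,
                "dt": self.dt, "noise_sd": self.noise_sd, "seed": int(base),
            }},
        )


def rule_homologue(model: GRNModel, gene: str, x) -> float | np.ndarray:
    """Functional alias for :meth:`GRNModel.rule_homologue`."""
    return model.rule_homologue(gene, x)


def simulate_trajectory(model: GRNModel, x0, n_steps: int, seed: int | None = None):
    return model.simulate_trajectory(x0, n_steps, seed=seed)


def sample_cells(model: GRNModel, x0, n_cells: int, n_steps: int, seed: int | None = None):
    return model.sample_cells(x0, n_cells, n_steps, seed=seed)


def toggle_switch(**kwargs) -> GRNModel:
    """Mutual-repression two-gene network (two stable attractors)."""
    return GRNModel(genes=["a", "b"], rules={"a": "NOT b", "b": "NOT a"}, **kwargs)


def read_model(path) -> GRNModel:
    """Read the plain-text model format: ``gene = expression`` per line."""
    genes: list[str] = []
    rules: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ModelError(f"line {lineno}: expected 'gene = expression'")
            name, expr = (s.strip() for s in line.split("=", 1))
            if name in rules:
                raise ModelError(f"line {lineno}: duplicate rule for {name!r}")
            genes.append(name)
            rules[name] = expr
    if not genes:
        raise ModelError("model file declares no genes")
    return GRNModel(genes=genes, rules=rules)


def write_model(model: GRNModel, path) -> None:
    with open(path, "w") as fh:
        for g in model.genes:
            fh.write(f"{g} = {model.rules[g]}\n")
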