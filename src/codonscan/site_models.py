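"""Site-class codon models, likelihood fitting and positive-selection tests.

The substitution process is the GY94 codon model: a reversible Markov chain
on the 61 sense codons whose instantaneous rate from codon i to j is nonzero
only for single-nucleotide changes and proportional to

    pi_j                      synonymous transversion
    kappa * pi_j              synonymous transition
    omega * pi_j              nonsynonymous transversion
    omega * kappa * pi_j      nonsynonymous transition

Variation of selective pressure across sites is modeled by a finite mixture
of omega classes:

* M0   — one omega for all sites;
* M1a  — nearly neutral: omega_0 < 1 and omega_1 = 1;
* M2a  — M1a plus a positive-selection class omega_2 >= 1;
* M7   — beta(p, q) distributed omega on (0, 1), discretized into K
         equal-probability classes;
* M8   — M7 plus one class with omega_s >= 1.

Log-likelihoods are computed by Felsenstein pruning on a fixed tree, with
transition matrices from the spectral decomposition of the reversible
generator, and maximized by quasi-Newton search on transformed parameters.
Positive selection is tested by likelihood-ratio tests of M1a-vs-M2a and
M7-vs-M8 (chi-square, df = 2), and individual sites are ranked by naive
empirical Bayes (NEB) posteriors over the fitted omega classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .codon_align import CodonAlignment
from .dnds import f3x4_frequencies
from .seqio import GAP_CODON, GeneticCode, NUCLEOTIDES, STANDARD_CODE
from .trees import PhyloTree

logger = logging.getLogger("codonscan")

DEFAULT_BETA_CLASSES = 10
POSITIVE_POSTERIOR_THRESHOLD = 0.5
STRONG_POSTERIOR_THRESHOLD = 0.95

#: free parameters per model (branch lengths excluded; shared across models)
MODEL_FREE_PARAMS = {"M0": 2, "M1a": 3, "M2a": 5, "M7": 3, "M8": 5}

#: nested (null, alternative) model pairs accepted by the LRT
NESTED_PAIRS = {("M0", "M1a"), ("M0", "M2a"), ("M1a", "M2a"), ("M7", "M8")}


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genetic-code tables for the generator
# ---------------------------------------------------------------------------


class _CodeTables:
    """Cached per-code arrays describing single-nucleotide codon changes."""

    _cache: dict[str, "_CodeTables"] = {}

    def __init__(self, code: GeneticCode):
        codons = code.sense_codons
        self.codons = codons
        self.index = {c: i for i, c in enumerate(codons)}
        n = len(codons)
        single = np.zeros((n, n), dtype=bool)
        transition = np.zeros((n, n), dtype=bool)
        synonymous = np.zeros((n, n), dtype=bool)
        ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for i, ci in enumerate(codons):
            for j, cj in enumerate(codons):
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                single[i, j] = True
                transition[i, j] = (ci[k], cj[k]) in ts_pairs
                synonymous[i, j] = code.translate_codon(ci) == code.translate_codon(cj)
        self.single = single
        self.transition = transition
        self.synonymous = synonymous

    @classmethod
    def get(cls, code: GeneticCode) -> "_CodeTables":
        if code.name not in cls._cache:
            cls._cache[code.name] = cls(code)
        return cls._cache[code.name]


def pi_array(pi, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Normalize a pi specification (dict, array or 'uniform') to a 61-vector."""
    codons = code.sense_codons
    if isinstance(pi, str):
        if pi != "uniform":
            raise ValueError(f"unknown pi specification {pi!r}")
        return np.full(len(codons), 1.0 / len(codons))
    if isinstance(pi, dict):
        vec = np.array([pi[c] for c in codons], dtype=float)
    else:
        vec = np.asarray(pi, dtype=float)
        if vec.shape != (len(codons),):
            raise ValueError(f"pi must have {len(codons)} entries")
    if abs(vec.sum() - 1.0) > 1e-6:
        raise ValueError("pi must sum to 1")
    return vec / vec.sum()


# ---------------------------------------------------------------------------
# Model parameter containers
# ---------------------------------------------------------------------------


@dataclass
class CodonModelParams:
    """Single-class GY94 parameters."""

    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa < 0 or self.omega < 0:
            raise ValueError("kappa and omega must be nonnegative")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")


@dataclass
class SiteClassSpec:
    """A finite mixture of omega classes (probabilities sum to 1)."""

    model_id: str
    probs: np.ndarray
    omegas: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.omegas = np.asarray(self.omegas, dtype=float)
        if self.probs.shape != self.omegas.shape:
            raise ValueError("probs and omegas must have equal length")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if np.any(self.probs < 0) or np.any(self.omegas < 0):
            raise ValueError("probabilities and omegas must be nonnegative")

    @classmethod
    def m0(cls, omega: float) -> "SiteClassSpec":
        return cls("M0", np.array([1.0]), np.array([omega]), {"omega": omega})

    @classmethod
    def m1a(cls, p0: float, w0: float) -> "SiteClassSpec":
        return cls("M1a", np.array([p0, 1.0 - p0]), np.array([w0, 1.0]), {"p0": p0, "w0": w0})

    @classmethod
    def m2a(cls, p0: float, p1: float, w0: float, w2: float) -> "SiteClassSpec":
        p2 = 1.0 - p0 - p1
        if p2 < -1e-12:
            raise ValueError("p0 + p1 must be <= 1")
        return cls(
            "M2a",
            np.array([p0, p1, max(p2, 0.0)]),
            np.array([w0, 1.0, w2]),
            {"p0": p0, "p1": p1, "w0": w0, "w2": w2},
        )

    @classmethod
    def m7(cls, p: float, q: float, K: int = DEFAULT_BETA_CLASSES) -> "SiteClassSpec":
        omegas = _beta_classes(p, q, K)
        return cls("M7", np.full(K, 1.0 / K), omegas, {"p": p, "q": q, "K": K})

    @classmethod
    def m8(
        cls, p0: float, p: float, q: float, ws: float, K: int = DEFAULT_BETA_CLASSES
    ) -> "SiteClassSpec":
        if ws < 1.0:
            raise ValueError("M8 selection-class omega must be >= 1")
        omegas = np.append(_beta_classes(p, q, K), ws)
        probs = np.append(np.full(K, p0 / K), 1.0 - p0)
        return cls("M8", probs, omegas, {"p0": p0, "p": p, "q": q, "ws": ws, "K": K})


def _beta_classes(p: float, q: float, K: int) -> np.ndarray:
    """K equal-probability beta(p, q) classes at their median quantiles."""
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    quantiles = (2.0 * np.arange(K) + 1.0) / (2.0 * K)
    omegas = beta_dist.ppf(quantiles, p, q)
    return np.clip(omegas, 1e-9, 1.0 - 1e-9)


@dataclass
class SiteModelFit:
    """Maximum-likelihood fit of one site-class model on a fixed tree."""

    model_id: str
    lnL: float
    kappa: float
    spec: SiteClassSpec
    branch_lengths: np.ndarray
    tree: PhyloTree
    pi: np.ndarray
    converged: bool
    n_free_params: int


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float


@dataclass
class SitePosterior:
    """NEB class posteriors for one codon column (1-based)."""

    site: int
    class_posteriors: np.ndarray
    posterior_mean_omega: float
    posterior_sd_omega: float
    p_positive: float
    flagged_positive: bool
    strong: bool


# ---------------------------------------------------------------------------
# Generator and transition matrices
# ---------------------------------------------------------------------------


def gy94_generator(params: CodonModelParams, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """GY94 rate generator, scaled to one expected substitution per codon site."""
    Q, rate = _build_q(params.kappa, params.omega, params.pi, code)
    if rate <= 0:
        raise ModelError("degenerate generator: zero substitution rate")
    return Q / rate


def _build_q(
    kappa: float, omega: float, pi: np.ndarray, code: GeneticCode
) -> tuple[np.ndarray, float]:
    if np.any(pi <= 0):
        raise ModelError("pi must be strictly positive for all sense codons")
    tables = _CodeTables.get(code)
    Q = np.where(tables.single, pi[None, :], 0.0)
    Q = np.where(tables.single & tables.transition, Q * kappa, Q)
    Q = np.where(tables.single & ~tables.synonymous, Q * omega, Q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = float(-(pi * np.diag(Q)).sum())
    return Q, rate


def build_site_class_matrices(
    probs: np.ndarray,
    omegas: np.ndarray,
    kappa: float,
    pi: np.ndarray,
    code: GeneticCode = STANDARD_CODE,
) -> list[np.ndarray]:
    """Per-class generators, jointly scaled so the mixture-average rate is 1.

    Branch lengths are therefore expected substitutions per codon site under
    the whole mixture (codeml's convention), not per class.
    """
    raw = []
    rates = []
    for omega in omegas:
        Q, rate = _build_q(kappa, omega, pi, code)
        raw.append(Q)
        rates.append(rate)
    mean_rate = float(np.dot(probs, rates))
    if mean_rate <= 0:
        raise ModelError("degenerate mixture: zero average substitution rate")
    return [Q / mean_rate for Q in raw]


class _Spectral:
    """Spectral decomposition of a reversible generator for fast P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self.lam = lam
        self.left = V / sqrt_pi[:, None]
        self.right = V.T * sqrt_pi[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        return np.clip(P, 0.0, None)


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible generator with stationary pi."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    return _Spectral(Q, pi).transition_matrix(t)


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------


class PruningEngine:
    """Felsenstein pruning over site patterns of a codon alignment on a tree.

    Gap codons are missing data (conditional likelihood 1 for every state).
    The engine owns a branch-length vector indexed by postorder node order
    (root excluded), which optimizers mutate.
    """

    def __init__(
        self,
        tree: PhyloTree,
        aln: CodonAlignment,
        code: GeneticCode = STANDARD_CODE,
        pi=None,
    ):
        if not tree.is_binary():
            raise ModelError("site models require a binary tree (root may be trifurcating)")
        if set(tree.leaf_names()) != set(aln.names):
            raise ModelError(
                f"tree leaves {sorted(tree.leaf_names())} do not match alignment "
                f"names {sorted(aln.names)}"
            )
        self.code = code
        self.tables = _CodeTables.get(code)
        self.tree = tree.copy()
        self.pi = pi_array(pi if pi is not None else f3x4_frequencies(aln.rows, code), code)

        nodes = self.tree.postorder()
        self.nodes = nodes
        self.node_index = {id(n): i for i, n in enumerate(nodes)}
        self.root_index = self.node_index[id(self.tree.root)]
        self.children = [
            [self.node_index[id(c)] for c in n.children] for n in nodes
        ]
        self.edge_nodes = [i for i, n in enumerate(nodes) if n is not self.tree.root]
        self.branch_lengths = np.array(
            [max(nodes[i].length or 0.0, 0.0) for i in self.edge_nodes], dtype=float
        )
        self.edge_of_node = {i: e for e, i in enumerate(self.edge_nodes)}

        # encode leaf states per site; -1 = missing (gap codon)
        states = {}
        for name, row in aln.rows:
            site_states = []
            for k in range(0, len(row), 3):
                codon = row[k : k + 3]
                if codon == GAP_CODON:
                    site_states.append(-1)
                else:
                    try:
                        site_states.append(self.tables.index[codon])
                    except KeyError:
                        raise ModelError(
                            f"row {name!r}: codon {codon!r} at position {k // 3 + 1} "
                            "is not a sense codon"
                        ) from None
            states[name] = np.array(site_states, dtype=int)
        self.n_sites = aln.ncodons
        leaf_order = [n.name for n in nodes if n.is_leaf]
        matrix = np.stack([states[name] for name in leaf_order])
        patterns, inverse, counts = np.unique(
            matrix, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_of_site = inverse.ravel()
        self.pattern_counts = counts.astype(float)
        self.leaf_patterns = {
            name: patterns[i] for i, name in enumerate(leaf_order)
        }
        self.n_patterns = patterns.shape[1]

    # -- likelihood ---------------------------------------------------------

    def _class_pattern_likelihoods(
        self, Qs: list[np.ndarray], bl: np.ndarray
    ) -> np.ndarray:
        """Per-class likelihood of every site pattern: shape (K, n_patterns)."""
        out = np.empty((len(Qs), self.n_patterns))
        nstates = len(self.pi)
        for ki, Q in enumerate(Qs):
            spectral = _Spectral(Q, self.pi)
            P = {}
            for e, i in enumerate(self.edge_nodes):
                P[i] = spectral.transition_matrix(bl[e])
            partial: dict[int, np.ndarray] = {}
            for i, node in enumerate(self.nodes):
                if node.is_leaf:
                    continue
                acc = np.ones((self.n_patterns, nstates))
                for c in self.children[i]:
                    child = self.nodes[c]
                    Pc = P[c]
                    if child.is_leaf:
                        s = self.leaf_patterns[child.name]
                        contrib = np.where(
                            (s == -1)[:, None], 1.0, Pc[:, np.where(s == -1, 0, s)].T
                        )
                    else:
                        contrib = partial.pop(c) @ Pc.T
                    acc *= contrib
                partial[i] = acc
            out[ki] = partial[self.root_index] @ self.pi
        return out

    def log_likelihood(
        self, probs: np.ndarray, omegas: np.ndarray, kappa: float, bl: np.ndarray | None = None
    ) -> float:
        bl = self.branch_lengths if bl is None else bl
        Qs = build_site_class_matrices(probs, omegas, kappa, self.pi, self.code)
        class_lik = self._class_pattern_likelihoods(Qs, bl)
        site_lik = np.asarray(probs) @ class_lik
        site_lik = np.clip(site_lik, 1e-300, None)
        return float(np.dot(np.log(site_lik), self.pattern_counts))

    def site_class_likelihoods(
        self, probs: np.ndarray, omegas: np.ndarray, kappa: float, bl: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-site per-class likelihoods, shape (K, n_sites) (NEB input)."""
        bl = self.branch_lengths if bl is None else bl
        Qs = build_site_class_matrices(probs, omegas, kappa, self.pi, self.code)
        class_lik = self._class_pattern_likelihoods(Qs, bl)
        return class_lik[:, self.pattern_of_site]


def site_log_likelihood(
    tree: PhyloTree,
    aln: CodonAlignment,
    spec: SiteClassSpec,
    kappa: float,
    pi=None,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Mixture log-likelihood of an alignment on a tree (branch lengths from the tree)."""
    engine = PruningEngine(tree, aln, code, pi)
    return engine.log_likelihood(spec.probs, spec.omegas, kappa)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Knobs for :func:`fit_model`.

    freqs: 'f3x4' (from the alignment) or 'uniform'. Branch lengths are
    estimated by ML under M0 and fixed for the site-class models
    ('m0-shared', the default); 'per-model' re-optimizes them in every fit.
    Multi-start restarts perturb the initial values with randomness derived
    from ``seed``.
    """

    freqs: str = "f3x4"
    n_starts: int = 3
    seed: int = 0
    optimize_branch_lengths: str = "m0-shared"
    branch_lengths: np.ndarray | None = None
    beta_classes: int = DEFAULT_BETA_CLASSES
    max_iter: int = 500
    lnl_tol: float = 1e-6


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1.0 - 1e-9)
    return float(np.log(p / (1.0 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


_BOUND_LOG = (-12.0, 6.0)
_BOUND_LOGIT = (-16.0, 16.0)
_BOUND_SHAPE = (-4.6, 4.6)  # beta shapes in ~[0.01, 100]
_BOUND_BL = (-18.0, 2.5)


class _ModelParameterization:
    """Pack/unpack between optimizer space and (probs, omegas, kappa)."""

    def __init__(self, model_id: str, K: int):
        self.model_id = model_id
        self.K = K

    def initial(self, rng: np.random.Generator | None) -> np.ndarray:
        jitter = (lambda: rng.normal(0.0, 0.5)) if rng is not None else (lambda: 0.0)
        k0 = np.log(2.0) + jitter()
        if self.model_id == "M0":
            x = [k0, np.log(0.4) + jitter()]
        elif self.model_id == "M1a":
            x = [k0, _logit(0.7) + jitter(), _logit(0.2) + jitter()]
        elif self.model_id == "M2a":
            x = [k0, 1.0 + jitter(), 0.5 + jitter(), _logit(0.2) + jitter(), np.log(1.5) + jitter()]
        elif self.model_id == "M7":
            x = [k0, np.log(0.5) + jitter(), np.log(1.5) + jitter()]
        elif self.model_id == "M8":
            x = [
                k0,
                _logit(0.9) + jitter(),
                np.log(0.5) + jitter(),
                np.log(1.5) + jitter(),
                np.log(1.0) + jitter(),
            ]
        else:
            raise ModelError(f"unknown model {self.model_id!r}")
        return np.array(x, dtype=float)

    def bounds(self) -> list[tuple[float, float]]:
        if self.model_id == "M0":
            return [_BOUND_LOG, _BOUND_LOG]
        if self.model_id == "M1a":
            return [_BOUND_LOG, _BOUND_LOGIT, _BOUND_LOGIT]
        if self.model_id == "M2a":
            return [_BOUND_LOG, _BOUND_LOGIT, _BOUND_LOGIT, _BOUND_LOGIT, _BOUND_LOG]
        if self.model_id == "M7":
            return [_BOUND_LOG, _BOUND_SHAPE, _BOUND_SHAPE]
        return [_BOUND_LOG, _BOUND_LOGIT, _BOUND_SHAPE, _BOUND_SHAPE, _BOUND_LOG]

    def unpack(self, x: np.ndarray) -> tuple[float, SiteClassSpec]:
        kappa = float(np.exp(x[0]))
        if self.model_id == "M0":
            return kappa, SiteClassSpec.m0(float(np.exp(x[1])))
        if self.model_id == "M1a":
            return kappa, SiteClassSpec.m1a(_expit(x[1]), _expit(x[2]))
        if self.model_id == "M2a":
            # stick-breaking simplex: logits for p0 and p1 | rest
            e = np.exp([x[1], x[2], 0.0])
            p = e / e.sum()
            return kappa, SiteClassSpec.m2a(
                float(p[0]), float(p[1]), _expit(x[3]), 1.0 + float(np.exp(x[4]))
            )
        if self.model_id == "M7":
            return kappa, SiteClassSpec.m7(float(np.exp(x[1])), float(np.exp(x[2])), self.K)
        return kappa, SiteClassSpec.m8(
            _expit(x[1]),
            float(np.exp(x[2])),
            float(np.exp(x[3])),
            1.0 + float(np.exp(x[4])),
            self.K,
        )


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model_id: str,
    options: FitOptions | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> SiteModelFit:
    """Maximum-likelihood fit of one site-class model.

    For M0 branch lengths are co-estimated (unless explicitly supplied). For
    the other models branch lengths are fixed: either given in
    ``options.branch_lengths``, or obtained by first fitting M0 internally
    ('m0-shared'); with ``optimize_branch_lengths='per-model'`` they are
    re-optimized in every fit.
    """
    options = options or FitOptions()
    model_id = _canonical_model_id(model_id)
    pi = pi_array("uniform" if options.freqs == "uniform" else f3x4_frequencies(aln.rows, code), code)
    engine = PruningEngine(tree, aln, code, pi)

    fixed_bl: np.ndarray | None = None
    if options.branch_lengths is not None:
        fixed_bl = np.asarray(options.branch_lengths, dtype=float)
        if fixed_bl.shape != engine.branch_lengths.shape:
            raise ModelError("branch_lengths vector does not match the tree's edge count")
    optimize_bl = model_id == "M0" or options.optimize_branch_lengths == "per-model"
    if fixed_bl is not None:
        optimize_bl = False
    if not optimize_bl and fixed_bl is None and model_id != "M0":
        m0 = fit_model(aln, tree, "M0", replace(options, branch_lengths=None), code)
        fixed_bl = m0.branch_lengths
    if fixed_bl is not None:
        engine.branch_lengths = fixed_bl.copy()

    par = _ModelParameterization(model_id, options.beta_classes)
    n_model = len(par.initial(None))
    bl0 = np.clip(engine.branch_lengths, 1e-6, None)
    rng = np.random.default_rng(options.seed)

    def objective(x: np.ndarray) -> float:
        kappa, spec = par.unpack(x[:n_model])
        bl = np.exp(x[n_model:]) if optimize_bl else engine.branch_lengths
        try:
            return -engine.log_likelihood(spec.probs, spec.omegas, kappa, bl)
        except (FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
            return 1e12

    best = None
    for start in range(max(options.n_starts, 1)):
        x0 = par.initial(rng if start else None)
        if optimize_bl:
            log_bl = np.log(bl0)
            if start:
                log_bl = log_bl + rng.normal(0.0, 0.3, size=log_bl.shape)
            x0 = np.concatenate([x0, log_bl])
        bounds = par.bounds() + ([_BOUND_BL] * len(bl0) if optimize_bl else [])
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.max_iter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun - options.lnl_tol:
            best = res
    assert best is not None

    kappa, spec = par.unpack(best.x[:n_model])
    bl = np.exp(best.x[n_model:]) if optimize_bl else engine.branch_lengths.copy()
    fitted_tree = engine.tree.copy()
    nodes = fitted_tree.postorder()
    for e, i in enumerate(engine.edge_nodes):
        nodes[i].length = float(bl[e])
    if not best.success:
        logger.warning("%s fit did not report convergence: %s", model_id, best.message)
    return SiteModelFit(
        model_id=model_id,
        lnL=float(-best.fun),
        kappa=kappa,
        spec=spec,
        branch_lengths=np.asarray(bl, dtype=float),
        tree=fitted_tree,
        pi=pi,
        converged=bool(best.success),
        n_free_params=MODEL_FREE_PARAMS[model_id],
    )


def _canonical_model_id(model_id: str) -> str:
    canonical = {m.lower(): m for m in MODEL_FREE_PARAMS}
    try:
        return canonical[model_id.lower()]
    except KeyError:
        raise ModelError(f"unknown model {model_id!r}; expected one of {list(MODEL_FREE_PARAMS)}")


def likelihood_ratio_test(null_fit: SiteModelFit, alt_fit: SiteModelFit) -> LRTResult:
    """LRT of nested site models: 2(lnL_alt - lnL_null) ~ chi-square.

    df is the difference in model free parameters (2 for M1a-vs-M2a and
    M7-vs-M8). No boundary mixture correction is applied, which makes the
    headline tests mildly conservative.
    """
    pair = (null_fit.model_id, alt_fit.model_id)
    if pair not in NESTED_PAIRS:
        raise ModelError(f"models {pair} are not a supported nested pair")
    statistic = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    df = alt_fit.n_free_params - null_fit.n_free_params
    p = float(chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return LRTResult(pair[0], pair[1], statistic, df, p)


def neb_site_posteriors(
    fit: SiteModelFit,
    aln: CodonAlignment,
    tree: PhyloTree | None = None,
    code: GeneticCode = STANDARD_CODE,
    threshold: float = POSITIVE_POSTERIOR_THRESHOLD,
) -> list[SitePosterior]:
    """Naive empirical Bayes per-site posteriors over the fitted omega classes.

    Class parameters are treated as known at their ML estimates (NEB; no
    integration over parameter uncertainty). A site is flagged positive when
    the posterior mass on classes with omega > 1 exceeds ``threshold``.
    """
    engine = PruningEngine(tree or fit.tree, aln, code, fit.pi)
    engine.branch_lengths = fit.branch_lengths.copy()
    class_lik = engine.site_class_likelihoods(fit.spec.probs, fit.spec.omegas, fit.kappa)
    joint = fit.spec.probs[:, None] * class_lik
    joint = np.clip(joint, 1e-300, None)
    post = joint / joint.sum(axis=0, keepdims=True)
    omegas = fit.spec.omegas
    positive_mask = omegas > 1.0
    out = []
    for site in range(post.shape[1]):
        ps = post[:, site]
        mean = float(np.dot(ps, omegas))
        var = float(np.dot(ps, (omegas - mean) ** 2))
        p_pos = float(ps[positive_mask].sum()) if positive_mask.any() else 0.0
        out.append(
            SitePosterior(
                site=site + 1,
                class_posteriors=ps,
                posterior_mean_omega=mean,
                posterior_sd_omega=float(np.sqrt(max(var, 0.0))),
                p_positive=p_pos,
                flagged_positive=p_pos > threshold,
                strong=p_pos > STRONG_POSTERIOR_THRESHOLD,
            )
        )
    return out


def fit_site_models(
    aln: CodonAlignment,
    tree: PhyloTree,
    models: tuple[str, ...] = ("M0", "M1a", "M2a", "M7", "M8"),
    options: FitOptions | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[dict[str, SiteModelFit], list[LRTResult]]:
    """Fit several site models sharing M0's branch lengths; run the headline LRTs.

    Returns the fits keyed by model id and the LRT results for every
    supported nested pair present among the fitted models.
    """
    options = options or FitOptions()
    models = tuple(_canonical_model_id(m) for m in models)
    fits: dict[str, SiteModelFit] = {}
    shared_bl = options.branch_lengths
    if shared_bl is None:
        m0 = fit_model(aln, tree, "M0", options, code)
        fits["M0"] = m0
        shared_bl = m0.branch_lengths
        shared_tree = m0.tree
    else:
        shared_tree = tree
    for model_id in models:
        if model_id in fits:
            continue
        fits[model_id] = fit_model(
            aln, shared_tree, model_id, replace(options, branch_lengths=shared_bl), code
        )
    lrts = [
        likelihood_ratio_test(fits[null], fits[alt])
        for null, alt in (("M1a", "M2a"), ("M7", "M8"), ("M0", "M1a"))
        if null in fits and alt in fits and null in models and alt in models
    ]
    return fits, lrts
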