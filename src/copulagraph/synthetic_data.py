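"""Ground-truth generators for mixed-type copula data.

Datasets are drawn in the generative direction of the copula model:
a latent vector Z ~ N(0, Omega_true^{-1}) (rescaled to unit variances)
is pushed through each variable's marginal — ordinal variables via
cutpoints placed at Phi^{-1} of cumulative level probabilities,
continuous variables via a prescribed monotone marginal (lognormal by
default, since nutrient intakes are right-skewed).  The sparse precision
matrix Omega_true is stored alongside every dataset so that edge
recovery, model selection, and bootstrap stability can be scored against
a known truth.

A nutrition-cohort template emulates a pooled intervention-study
structure: four one-hot study blocks (252/122/81/207 subjects, 662
total), right-skewed nutrient intakes, 0-4 and 0-12 ordinal
physical-functioning scores, and binary sex/smoking covariates with
the pooled marginal means and SDs of the combined cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .data_io import MixedDataset, VariableSpec
from .selection_stability import partial_correlations


@dataclass
class TruthGraph:
    """A known sparse positive-definite precision matrix with the variable
    specs used to transform latent draws into observations."""

    omega_true: np.ndarray
    specs: list[VariableSpec]

    def __post_init__(self):
        self.omega_true = np.asarray(self.omega_true, dtype=float)
        w = np.linalg.eigvalsh(self.omega_true)
        if w.min() <= 0:
            raise ValueError("truth precision must be positive definite")

    @property
    def p(self) -> int:
        return self.omega_true.shape[0]

    @property
    def support(self) -> np.ndarray:
        s = self.omega_true != 0.0
        np.fill_diagonal(s, False)
        return s

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        iu = np.triu_indices(self.p, 1)
        keep = self.omega_true[iu] != 0.0
        return set(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))


def mixed_specs(p: int, vtype: str = "ordinal", n_levels: int = 3,
                probs=None, group: str = "other") -> list[VariableSpec]:
    """Homogeneous spec list for simulation fixtures.

    Ordinal/binary variables get level probabilities ``probs`` (uniform by
    default); continuous variables get the identity (latent-scale) marginal.
    """
    specs = []
    for j in range(p):
        name = f"v{j}"
        if vtype == "continuous":
            specs.append(VariableSpec(name, "continuous", group=group))
        else:
            K = 2 if vtype == "binary" else n_levels
            pr = list(probs) if probs is not None else [1.0 / K] * K
            specs.append(VariableSpec(name, vtype, levels=list(range(K)),
                                      group=group, marginal={"probs": pr}))
    return specs


# ---------------------------------------------------------------------------
# precision-matrix generation


def _support_pairs(p: int, structure: str, n_edges: int,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    if structure == "chain":
        return [(i, i + 1) for i in range(p - 1)]
    if structure == "hub":
        return [(0, j) for j in range(1, p)]
    if structure == "random":
        iu = np.transpose(np.triu_indices(p, 1))
        pick = rng.choice(len(iu), size=n_edges, replace=False)
        return [tuple(iu[k]) for k in pick]
    raise ValueError(f"unknown structure {structure!r}")


def random_sparse_precision(p: int, sparsity: float = 0.1,
                            strength: tuple[float, float] = (0.3, 0.5),
                            structure: str = "random",
                            seed: int | None = None, *,
                            specs: list[VariableSpec] | None = None,
                            max_tries: int = 100,
                            min_eig: float = 0.15) -> TruthGraph:
    """Sparse PD precision with edge partial correlations in ``strength``.

    The support is drawn per ``structure`` (for chain/hub the target
    sparsity is implied by the structure); off-diagonal entries are set to
    minus a partial correlation drawn from +/-[strength].  The matrix is
    kept well conditioned (smallest eigenvalue >= ``min_eig``) by
    shrinking the off-diagonal toward the identity when needed; a truth
    graph close to singular would be unrecoverable by any method and
    makes a meaningless fixture.  If shrinkage collapses edge magnitudes
    below the requested range (minus a logged 0.05 tolerance) the support
    is redrawn; after ``max_tries`` failures the combination is declared
    infeasible.
    """
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    lo, hi = strength
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError("strength range must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    n_edges = int(round(sparsity * p * (p - 1) / 2))
    if specs is None:
        specs = mixed_specs(p, "continuous")
    if structure == "random" and n_edges == 0:
        return TruthGraph(np.eye(p), specs)
    for _ in range(max_tries):
        pairs = _support_pairs(p, structure, n_edges, rng)
        omega = np.eye(p)
        for (i, j) in pairs:
            rho = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            omega[i, j] = omega[j, i] = -rho
        for _ in range(10):
            if np.linalg.eigvalsh(omega).min() >= min_eig:
                break
            off = omega - np.diag(np.diag(omega))
            omega = np.eye(p) + off * 0.95
        if np.linalg.eigvalsh(omega).min() < min_eig:
            continue
        partials = partial_correlations(omega)
        mags = np.array([abs(partials[i, j]) for (i, j) in pairs])
        if mags.min() >= lo - 0.05:
            return TruthGraph(omega, specs)
    raise ValueError("infeasible sparsity/strength combination: positive-"
                     "definiteness forces edge magnitudes below the "
                     "requested range")


# ---------------------------------------------------------------------------
# sampling


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def _apply_marginal(z: np.ndarray, spec: VariableSpec) -> np.ndarray:
    """Push a standard-normal latent column through the spec's marginal."""
    marg = spec.marginal or {}
    if spec.is_discrete:
        probs = np.asarray(marg.get("probs",
                                    [1.0 / spec.n_levels] * spec.n_levels))
        cuts = ndtri(np.cumsum(probs)[:-1])
        return np.searchsorted(cuts, z, side="left").astype(float)
    dist = marg.get("dist", "identity")
    if dist == "identity":
        return z
    mean, sd = float(marg["mean"]), float(marg["sd"])
    if dist == "lognormal":
        mu, s = _lognormal_params(mean, sd)
        return np.exp(mu + s * z)
    if dist == "normal":
        return mean + sd * z
    if dist == "gamma":
        shape = (mean / sd) ** 2
        scale = sd ** 2 / mean
        return stats.gamma.ppf(ndtr(z), shape, scale=scale)
    raise ValueError(f"unknown continuous marginal {dist!r}")


def _latent_correlation(omega: np.ndarray) -> np.ndarray:
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def sample_copula_data(truth: TruthGraph, n: int, seed: int | None = None,
                       missing_rate: float = 0.0) -> MixedDataset:
    """Draw n subjects from the copula model implied by ``truth``.

    Latent vectors come from N(0, Omega_true^{-1}) rescaled to unit
    variances; each coordinate is transformed by its spec's marginal, and
    cells are then masked completely at random at ``missing_rate``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    corr = _latent_correlation(truth.omega_true)
    L = np.linalg.cholesky(corr)
    Z = rng.standard_normal((n, truth.p)) @ L.T
    values = np.column_stack([
        _apply_marginal(Z[:, j], spec) for j, spec in enumerate(truth.specs)])
    mask = np.zeros((n, truth.p), dtype=bool)
    if missing_rate > 0:
        mask = rng.random((n, truth.p)) < missing_rate
        values = values.copy()
        values[mask] = np.nan
    return MixedDataset(values, truth.specs, mask)


# ---------------------------------------------------------------------------
# nutrition-cohort template


def _discretized_normal_probs(n_levels: int, mean: float, sd: float
                              ) -> np.ndarray:
    """Level probabilities for scores 0..K-1 from a discretized normal whose
    location is calibrated so the discrete mean hits ``mean`` exactly."""
    k = np.arange(n_levels)

    def disc_mean(mu):
        pr = ndtr((k + 0.5 - mu) / sd) - ndtr((k - 0.5 - mu) / sd)
        pr = np.maximum(pr, 1e-12)
        pr = pr / pr.sum()
        return float(np.sum(k * pr))

    lo, hi = -5.0 * sd, (n_levels - 1) + 5.0 * sd
    mu = brentq(lambda m: disc_mean(m) - mean, lo, hi)
    pr = ndtr((k + 0.5 - mu) / sd) - ndtr((k - 0.5 - mu) / sd)
    pr = np.maximum(pr, 1e-12)
    return pr / pr.sum()


def _ordinal_spec(name, n_levels, mean, sd, group):
    probs = _discretized_normal_probs(n_levels, mean, sd)
    return VariableSpec(name, "ordinal", levels=list(range(n_levels)),
                        group=group,
                        marginal={"probs": probs.tolist(),
                                  "target_mean": mean, "target_sd": sd})


def _binary_spec(name, prob_one, group):
    return VariableSpec(name, "binary", levels=[0, 1], group=group,
                        marginal={"probs": [1.0 - prob_one, prob_one],
                                  "target_mean": prob_one})


def _cont_spec(name, mean, sd, group, dist="lognormal"):
    return VariableSpec(name, "continuous", group=group,
                        marginal={"dist": dist, "mean": mean, "sd": sd,
                                  "target_mean": mean, "target_sd": sd})


# pooled-cohort marginal targets (combined column): mean, sd
_NUTRIENTS = {
    "energy": (1913, 469), "animal_protein": (46, 15),
    "vegetable_protein": (28, 9), "fat": (75, 24), "saturated_fat": (30, 11),
    "starch": (105, 33), "sugar": (106, 41), "fiber": (22, 7),
    "thiamin": (1.0, 0.5), "riboflavin": (1.4, 0.5), "vitamin_b6": (1.5, 0.7),
    "folate": (243, 85), "vitamin_b12": (4.5, 2.7), "vitamin_c": (104, 54),
    "vitamin_d": (3.6, 2.3), "calcium": (992, 346), "magnesium": (318, 90),
}

_STUDY_BLOCKS = {"study_a": 252, "study_b": 122, "study_c": 81,
                 "study_d": 207}

# default truth edges of the template (name_i, name_j, signed partial corr)
_DEFAULT_COHORT_EDGES = [
    ("vegetable_protein", "sppb_total", 0.3),
    ("vitamin_b6", "sppb_total", 0.25),
    ("folate", "sppb_total", 0.2),
    ("vegetable_protein", "sppb_chair", 0.3),
    ("vitamin_b6", "sppb_chair", 0.2),
    ("vitamin_b12", "sppb_chair", 0.2),
    ("age", "handgrip", -0.25),
    ("sex", "handgrip", -0.3),
    ("height", "handgrip", 0.25),
    ("weight", "handgrip", 0.25),
    ("alcohol", "handgrip", 0.2),
    ("sex", "alcohol", -0.2),
    ("sex", "energy", -0.25),
    ("sex", "starch", -0.2),
    ("folate", "bmi", -0.2),
    ("vitamin_b12", "weight", 0.2),
]


@dataclass
class CohortTemplate:
    """Marginal targets and block structure of the pooled synthetic cohort."""

    specs: list[VariableSpec]
    block_sizes: dict[str, int]
    edges: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(_DEFAULT_COHORT_EDGES))

    @property
    def n(self) -> int:
        return sum(self.block_sizes.values())

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def truth_graph(self) -> TruthGraph:
        """Precision matrix with the template's named edges; study-dummy
        rows stay diagonal (the blocks are deterministic, not sampled)."""
        names = self.names
        p = len(names)
        idx = {nm: j for j, nm in enumerate(names)}
        omega = np.eye(p)
        for (a, b, rho) in self.edges:
            i, j = idx[a], idx[b]
            omega[i, j] = omega[j, i] = -rho
        shrink_steps = 0
        while np.linalg.eigvalsh(omega).min() < 0.15 and shrink_steps < 60:
            off = omega - np.diag(np.diag(omega))
            omega = np.eye(p) + off * 0.95
            shrink_steps += 1
        return TruthGraph(omega, self.specs)


def cohort_template() -> CohortTemplate:
    """The pooled nutrition-cohort template: 33 variables, 662 subjects in
    four study blocks (252/122/81/207), Tables-style marginals."""
    specs = [
        _cont_spec("age", 75, 7, "covariate", dist="normal"),
        _binary_spec("sex", 0.617, "covariate"),
        _cont_spec("bmi", 25.3, 3.8, "covariate", dist="normal"),
        _cont_spec("height", 167, 9, "covariate", dist="normal"),
        _cont_spec("weight", 71, 13, "covariate", dist="normal"),
        _cont_spec("alcohol", 9.4, 12.3, "covariate", dist="lognormal"),
        _binary_spec("smoking", 0.309, "covariate"),
        _cont_spec("handgrip", 26, 9, "physical_functioning", dist="normal"),
        _ordinal_spec("sppb_total", 13, 9.6, 2.5, "physical_functioning"),
        _ordinal_spec("sppb_balance", 5, 3.5, 0.9, "physical_functioning"),
        _ordinal_spec("sppb_chair", 5, 2.6, 1.4, "physical_functioning"),
        _ordinal_spec("sppb_gait", 5, 3.5, 0.9, "physical_functioning"),
    ]
    for name, (mean, sd) in _NUTRIENTS.items():
        specs.append(_cont_spec(name, mean, sd, "nutrient"))
    for name in _STUDY_BLOCKS:
        specs.append(VariableSpec(name, "binary", levels=[0, 1],
                                  group="study_dummy"))
    return CohortTemplate(specs=specs, block_sizes=dict(_STUDY_BLOCKS))


def sample_cohort(template: CohortTemplate | None = None,
                  seed: int | None = None, missing_rate: float = 0.0,
                  n: int | None = None
                  ) -> tuple[MixedDataset, TruthGraph]:
    """Generate a synthetic pooled cohort from the template.

    Stochastic variables follow the copula model under the template's
    truth graph; the four study-dummy columns are deterministic one-hot
    block indicators (scaled proportionally if ``n`` overrides the
    default 662).  Masking is completely at random over the stochastic
    columns; dummy columns are never masked.
    """
    tpl = template or cohort_template()
    truth = tpl.truth_graph()
    names = tpl.names
    n_total = tpl.n if n is None else int(n)
    sizes = list(tpl.block_sizes.values())
    if n is not None and n_total != tpl.n:
        raw = np.array(sizes, dtype=float) * n_total / sum(sizes)
        sizes = np.maximum(np.floor(raw).astype(int), 1)
        sizes[0] += n_total - sizes.sum()
        sizes = sizes.tolist()
    rng = np.random.default_rng(seed)
    data = sample_copula_data(truth, n_total, seed=rng.integers(2**31),
                              missing_rate=0.0)
    values = data.values.copy()
    mask = np.zeros_like(values, dtype=bool)
    dummy_idx = [names.index(nm) for nm in tpl.block_sizes]
    starts = np.cumsum([0] + sizes[:-1])
    for j, start, size in zip(dummy_idx, starts, sizes):
        values[:, j] = 0.0
        values[start:start + size, j] = 1.0
    if missing_rate > 0:
        stoch = [j for j in range(len(names)) if j not in dummy_idx]
        mask[:, stoch] = rng.random((n_total, len(stoch))) < missing_rate
        values[mask] = np.nan
    return MixedDataset(values, tpl.specs, mask), truth


# ---------------------------------------------------------------------------
# scoring


def edge_recovery_metrics(truth: TruthGraph, estimate
                          ) -> tuple[float, float, float]:
    """Support precision/recall/F1 of an estimated graph against the truth.

    ``estimate`` may be a SelectedNetwork, a PrecisionEstimate, or a raw
    precision matrix.  An empty estimate against a nonempty truth scores
    (0, 0, 0) by convention.
    """
    omega = getattr(estimate, "omega", estimate)
    omega = np.asarray(omega)
    if omega.shape != truth.omega_true.shape:
        raise ValueError("dimension mismatch between truth and estimate")
    iu = np.triu_indices(truth.p, 1)
    est = omega[iu] != 0.0
    true = truth.omega_true[iu] != 0.0
    tp = int(np.sum(est & true))
    fp = int(np.sum(est & ~true))
    fn = int(np.sum(~est & true))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return precision, recall, f1
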