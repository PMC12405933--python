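"""Synthetic severe-asthma cohorts from a ground-truth pathway network.

The generator emulates a specialist-registry population of biologic-naive
adults with severe asthma.  A directed acyclic pathway network over clinical
band variables (age band, sex, chronic rhinosinusitis status, macrolide use,
blood eosinophil count, Feno, % predicted FEV₁, IgE, prior and future severe
exacerbations) defines the joint distribution; continuous measurements are
then drawn within the sampled band.  Because every dependency flows through
the clinical bands, discretising a cohort at the same cut points yields data
that are *exactly* Markov with respect to the ground-truth DAG — downstream
structure-learning results therefore have a known truth.

Marginal structure is calibrated to the registry population this emulates:
61.2% female, 31.1% CRS with nasal polyps, 11.9% macrolide use, age
55.2 ± 15.1 y, % predicted FEV₁ 73.6 ± 20.0, Feno 41.8 ± 32.7 ppb, blood
eosinophils 426.4 ± 326.2 cells/μL, IgE 406.7 ± 884.9 kU/L, 0.5 prior and 0.2
future severe exacerbations per 12 months.  Band intercepts are solved by
bisection at build time so these marginals hold exactly under the configured
effects.

Exacerbation counts arise from a latent negative-binomial rate per parent
configuration, thresholded to the 3-level outcome {0, 1, ≥2}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import CycleError, NetworkStructure

__all__ = [
    "GroundTruthSpec", "MissingnessRule", "CountryBlock",
    "make_ground_truth_network", "sample_cohort", "inject_missingness",
    "assign_country", "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "crs", "bec", "feno", "fev1pp", "ige",
    "fev1_reversibility", "er_visits", "invasive_ventilation", "lama",
    "macrolide", "anxiety", "eczema", "prior_exac", "country", "future_exac",
]

# Table-1-style marginal targets of the emulated registry population
_TARGETS = {
    "female": 0.612,
    "crs_any": 0.511,        # 31.1% with NP + 20.0% without NP
    "crs_wnp": 0.311,
    "macrolide": 0.119,
    "prior_mean": 0.5,
    "future_mean": 0.2,
    "lama": 0.083,
    "anxiety": 0.074,
    "eczema": 0.141,
    "invasive_ventilation": 0.01,
    "er_mean": 0.2,
}

_NB_SIZE = 6.0   # negative-binomial dispersion of the latent exacerbation rate


# ---------------------------------------------------------------------------
# spec containers
# ---------------------------------------------------------------------------

@dataclass
class MissingnessRule:
    column: str
    rate: float
    mechanism: str = "mcar"          # "mcar" | "mar"
    driver: str | None = None        # fully-observed column driving MAR
    odds: float = 1.0                # per-driver-level odds multiplier

    def validate(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError(f"missingness rate for {self.column} not in [0,1)")
        if self.mechanism not in ("mcar", "mar"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "mar" and not self.driver:
            raise ValueError("MAR rule needs a driver column")
        if self.mechanism == "mar" and self.driver == self.column:
            raise ValueError("MAR driver cannot be the masked column itself")


@dataclass
class CountryBlock:
    k: int = 10
    effect_sd: float = 0.2
    multipliers: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.multipliers:
            # deterministic multipliers from equally spaced normal quantiles
            z = stats.norm.ppf((np.arange(self.k) + 0.5) / self.k)
            self.multipliers = tuple(np.exp(self.effect_sd * z))
        if len(self.multipliers) != self.k:
            raise ValueError("need one multiplier per country")

    @property
    def labels(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.k)]


@dataclass
class ContinuousEmission:
    """Within-band distribution of an observed continuous measurement."""
    family: str                      # "lognormal" | "normal"
    params: tuple[float, float]      # (mu, sigma) on the latent scale
    cuts: tuple[float, ...]          # strictly increasing band boundaries
    support: tuple[float, float] = (0.0, np.inf)

    def _dist(self):
        mu, sigma = self.params
        if self.family == "lognormal":
            return stats.lognorm(s=sigma, scale=np.exp(mu))
        if self.family == "normal":
            return stats.norm(loc=mu, scale=sigma)
        raise ValueError(f"unknown family {self.family!r}")

    def band_probs(self) -> np.ndarray:
        """Band probabilities implied by the marginal distribution."""
        d = self._dist()
        lo, hi = self.support
        edges = [lo, *self.cuts, hi]
        cdf = d.cdf(edges)
        p = np.diff(cdf) / max(cdf[-1] - cdf[0], 1e-300)
        return p / p.sum()

    def sample(self, bands: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        d = self._dist()
        lo, hi = self.support
        edges = np.array([lo, *self.cuts, hi], dtype=float)
        flo = d.cdf(edges[bands])
        fhi = d.cdf(edges[bands + 1])
        u = rng.uniform(flo, fhi)
        vals = d.ppf(np.clip(u, 1e-12, 1 - 1e-12))
        return np.clip(vals, lo, min(hi, np.finfo(float).max))


@dataclass
class GroundTruthSpec:
    """Discrete pathway network plus emissions, country and missingness blocks."""

    nodes: list[str]                                   # topological order
    levels: dict[str, list]                            # node -> level labels
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]                        # (*parent cards, r)
    emissions: dict[str, ContinuousEmission] = field(default_factory=dict)
    country: CountryBlock = field(default_factory=CountryBlock)
    missingness: list[MissingnessRule] = field(default_factory=list)
    name: str = "custom"
    # latent NB rate per parent configuration of the outcome (multiplier 1);
    # kept so sampling and the stored country-mixture CPT agree exactly
    latent_future_rate: np.ndarray | None = None

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        g = self.dag()                                 # raises on cycles
        order = {n: i for i, n in enumerate(self.nodes)}
        for n in self.nodes:
            for p in self.parents.get(n, ()):
                if order[p] >= order[n]:
                    raise ValueError(f"nodes not topologically ordered at {p}->{n}")
        for n, cpt in self.cpts.items():
            want = tuple(len(self.levels[p]) for p in self.parents.get(n, ())) \
                + (len(self.levels[n]),)
            if cpt.shape != want:
                raise ValueError(f"CPT shape mismatch for {n}: {cpt.shape} != {want}")
            rows = cpt.reshape(-1, cpt.shape[-1])
            if np.any(rows < -1e-15):
                raise ValueError(f"negative probability in CPT of {n}")
            if np.max(np.abs(rows.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"CPT rows of {n} do not sum to 1")
        for r in self.missingness:
            r.validate()
            if r.mechanism == "mar" and any(
                    m.column == r.driver for m in self.missingness):
                raise ValueError(
                    f"MAR driver {r.driver!r} is itself targeted for masking")
        _ = g

    def dag(self) -> NetworkStructure:
        arcs = {(p, n) for n in self.nodes for p in self.parents.get(n, ())}
        g = NetworkStructure(tuple(self.nodes), arcs)
        if not g.is_dag():
            raise CycleError("ground-truth arc set is cyclic")
        return g

    # -- exact joint over bands ---------------------------------------------
    def joint(self) -> np.ndarray:
        """Exact joint probability table over band levels (node order = axes)."""
        cards = [len(self.levels[n]) for n in self.nodes]
        pos = {n: i for i, n in enumerate(self.nodes)}
        joint = np.ones((), dtype=np.float64)
        for i, n in enumerate(self.nodes):
            ps = self.parents.get(n, ())
            cpt = self.cpts[n]
            # reorder parent axes by their joint position, then broadcast
            axes_order = sorted(range(len(ps)), key=lambda j: pos[ps[j]])
            reordered = np.transpose(cpt, axes_order + [len(ps)])
            view_shape = [1] * (i + 1)
            for p in ps:
                view_shape[pos[p]] = cards[pos[p]]
            view_shape[i] = cards[i]
            expand = reordered.reshape(view_shape)
            joint = joint[..., None] * expand
        return joint

    def marginal(self, node: str) -> np.ndarray:
        j = self.joint()
        i = self.nodes.index(node)
        axes = tuple(a for a in range(len(self.nodes)) if a != i)
        return j.sum(axis=axes)

    # -- band helpers -------------------------------------------------------
    def band_of(self, node: str, values: np.ndarray) -> np.ndarray:
        """Map continuous values to band codes with the spec's cuts."""
        em = self.emissions[node]
        return np.searchsorted(np.asarray(em.cuts), np.asarray(values),
                               side="right").astype(np.int64)

    def discretize(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Band-level view of the cohort over the spec's nodes."""
        out = {}
        for n in self.nodes:
            if n in self.emissions:
                codes = self.band_of(n, cohort[n].to_numpy())
                out[n] = pd.Categorical.from_codes(
                    codes, categories=[str(l) for l in self.levels[n]])
            else:
                out[n] = pd.Categorical(
                    cohort[n].astype(str),
                    categories=[str(l) for l in self.levels[n]])
        return pd.DataFrame(out, index=cohort.index)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "nodes": self.nodes,
            "levels": {n: [str(l) for l in v] for n, v in self.levels.items()},
            "parents": {n: list(p) for n, p in self.parents.items()},
            "cpts": {n: c.tolist() for n, c in self.cpts.items()},
            "emissions": {
                n: {"family": e.family, "params": list(e.params),
                    "cuts": list(e.cuts), "support": list(e.support)}
                for n, e in self.emissions.items()},
            "country": {"k": self.country.k, "effect_sd": self.country.effect_sd,
                        "multipliers": list(self.country.multipliers)},
            "missingness": [
                {"column": r.column, "rate": r.rate, "mechanism": r.mechanism,
                 "driver": r.driver, "odds": r.odds}
                for r in self.missingness],
        }
        if self.latent_future_rate is not None:
            payload["latent_future_rate"] = self.latent_future_rate.tolist()
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthSpec":
        d = json.loads(text)
        return cls(
            nodes=list(d["nodes"]),
            levels={n: list(v) for n, v in d["levels"].items()},
            parents={n: tuple(p) for n, p in d["parents"].items()},
            cpts={n: np.asarray(c, dtype=float) for n, c in d["cpts"].items()},
            emissions={
                n: ContinuousEmission(e["family"], tuple(e["params"]),
                                      tuple(e["cuts"]),
                                      tuple(e["support"]))
                for n, e in d.get("emissions", {}).items()},
            country=CountryBlock(d["country"]["k"], d["country"]["effect_sd"],
                                 tuple(d["country"]["multipliers"])),
            missingness=[MissingnessRule(**r) for r in d.get("missingness", [])],
            name=d.get("name", "custom"),
            latent_future_rate=(
                np.asarray(d["latent_future_rate"], dtype=float)
                if "latent_future_rate" in d else None),
        )


# ---------------------------------------------------------------------------
# CPT builders (calibrated at build time)
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _bisect(fun, lo=-30.0, hi=30.0, tol=1e-12, iters=200):
    flo, fhi = fun(lo), fun(hi)
    if flo * fhi > 0:
        raise ValueError("bisection bracket does not straddle the root")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = fun(mid)
        if abs(fm) < tol:
            return mid
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def _ordered_logit_cpt(eta: np.ndarray, weights: np.ndarray,
                       cum_targets: tuple[float, ...]) -> np.ndarray:
    """CPT over r = len(cum_targets)+1 ordered bands from a latent logit.

    ``eta`` has one entry per parent configuration (higher eta pushes mass to
    higher bands); ``weights`` is the parent-configuration distribution.
    Thresholds are solved so the *marginal* cumulative band probabilities hit
    ``cum_targets`` exactly.
    """
    shape = eta.shape
    eta = eta.reshape(-1)
    w = weights.reshape(-1)
    w = w / w.sum()
    thresholds = []
    for tgt in cum_targets:
        t = _bisect(lambda t: float(np.sum(w * _sigmoid(t - eta))) - tgt)
        thresholds.append(t)
    cum = np.stack([_sigmoid(t - eta) for t in thresholds], axis=-1)
    cum = np.minimum.accumulate(cum[..., ::-1], axis=-1)[..., ::-1]  # enforce order
    cum = np.concatenate([cum, np.ones_like(cum[..., :1])], axis=-1)
    probs = np.diff(np.concatenate([np.zeros_like(cum[..., :1]), cum], axis=-1),
                    axis=-1)
    probs = np.clip(probs, 1e-12, None)
    probs /= probs.sum(axis=-1, keepdims=True)
    return probs.reshape(*shape, len(cum_targets) + 1)


def _binary_logit_cpt(eta: np.ndarray, weights: np.ndarray,
                      target: float) -> np.ndarray:
    shape = eta.shape
    eta_f = eta.reshape(-1)
    w = weights.reshape(-1)
    w = w / w.sum()
    b = _bisect(lambda b: float(np.sum(w * _sigmoid(b + eta_f))) - target)
    p1 = _sigmoid(b + eta_f)
    return np.stack([1 - p1, p1], axis=-1).reshape(*shape, 2)


def _nb_levels(lam: np.ndarray, size: float = _NB_SIZE) -> np.ndarray:
    """P(count = 0, 1, ≥2) under a negative binomial with mean ``lam``."""
    lam = np.asarray(lam, dtype=float)
    p = size / (size + lam)
    p0 = p ** size
    p1 = size * (1 - p) * p0
    p2 = np.clip(1.0 - p0 - p1, 1e-12, None)
    out = np.stack([p0, p1, p2], axis=-1)
    return out / out.sum(axis=-1, keepdims=True)


def _nb_count_cpt(eta: np.ndarray, weights: np.ndarray, target_mean: float,
                  multipliers: tuple[float, ...] = (1.0,),
                  cap: float | None = None) -> np.ndarray:
    """Outcome CPT from a latent negative-binomial rate min(λ0·exp(eta), cap).

    ``multipliers`` are country rate multipliers; the CPT is the equal-weight
    country mixture, and λ0 is solved so the expected count (including the
    country mixture) equals ``target_mean``.  The cap bounds the per-patient
    annual rate: without it the calibrated mean is spent on a few extreme
    configurations' high counts instead of on distinct exacerbators.
    """
    w = weights.reshape(-1)
    w = w / w.sum()
    mean_mult = float(np.mean(multipliers))
    e = np.exp(eta.reshape(-1))
    if cap is None:
        lam0 = target_mean / (float(np.sum(w * e)) * mean_mult)
    else:
        lam0 = _bisect(
            lambda ll: float(np.sum(w * np.minimum(np.exp(ll) * e, cap)))
            * mean_mult - target_mean, lo=-40.0, hi=10.0)
        lam0 = float(np.exp(lam0))
    rates = lam0 * np.exp(eta)
    if cap is not None:
        rates = np.minimum(rates, cap)
    cpt = np.zeros((*eta.shape, 3))
    for m in multipliers:
        cpt += _nb_levels(rates * m)
    cpt /= len(multipliers)
    return cpt, rates


def _effect(levels_card: int, values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (levels_card,):
        raise ValueError("effect vector length mismatch")
    return v


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Per-parent-level effects on the latent scales (log-odds / log-rate).  These
# magnitudes were fixed by an a-priori identifiability analysis at the design
# cohort size n = 20,000: every arc's conditional mutual information must
# clear both the BIC add/delete margin and the G² critical value at the
# dimension of its conditioning set (see docs/methods.md).
_EFFECTS = {
    "crs_any_age": (0.0, 1.2, 2.0),
    "crs_any_sex": (1.5, 0.0),              # (Female, Male)
    "crs_wnp_age": (0.0, 0.3, 0.5),
    "crs_wnp_sex": (0.0, 0.5),
    "macrolide_age": (0.0, 0.7, 1.2),
    "bec_crs": (0.0, 1.1, 2.2),              # (None, CRSwoNP, CRSwNP)
    "fev_crs": (0.0, -0.9, -1.8),
    "feno_crs": (0.0, 0.8, 1.6),
    "feno_fev": (2.2, 1.1, 0.0),            # (low, mid, high FEV1pp)
    "feno_bec": (0.0, 0.9, 1.8),
    "prior_bec": (0.0, 0.6, 1.2),
    "prior_feno": (0.0, 0.9, 1.8),
    "prior_fev": (1.8, 0.9, 0.0),
    "future_prior": (0.0, 1.4, 2.6),
    "future_bec": (0.0, 1.7, 3.4),
    "future_feno": (0.0, 1.1, 2.2),
    "future_fev": (3.4, 1.7, 0.0),
    "future_macrolide": (0.0, 2.6),
    # extended15 children
    "er_prior": (0.0, 1.2, 2.2),
    "invvent_prior": (0.0, 1.0, 1.8),
    "lama_fev": (1.0, 0.5, 0.0),
    "anxiety_prior": (0.0, 0.6, 1.0),
    "eczema_crs": (0.0, 0.4, 0.6),
}

_EMISSIONS = {
    "age": ContinuousEmission("normal", (55.2, 15.1), (40.0, 60.0), (18.0, 100.0)),
    "bec": ContinuousEmission("lognormal", (5.8253, 0.6790), (150.0, 300.0)),
    "feno": ContinuousEmission("lognormal", (3.4942, 0.6914), (25.0, 50.0)),
    "fev1pp": ContinuousEmission("normal", (73.6, 20.0), (60.0, 80.0), (1.0, 200.0)),
    "ige": ContinuousEmission("lognormal", (5.1354, 1.3218), (150.0, 600.0)),
}

_DEFAULT_MISSINGNESS = [
    MissingnessRule("bec", 0.06),
    MissingnessRule("feno", 0.10),
    MissingnessRule("ige", 0.12),
    MissingnessRule("fev1pp", 0.04),
    MissingnessRule("fev1_reversibility", 0.10),
]


def _build_preset(name: str, macrolide_to_prior: bool = False) -> GroundTruthSpec:
    country = CountryBlock()
    nodes = ["age", "sex", "crs", "macrolide", "bec", "fev1pp", "feno", "ige",
             "prior_exac", "future_exac"]
    levels = {
        "age": ["<40", "40-60", ">60"],
        "sex": ["Female", "Male"],
        "crs": ["None", "CRSwoNP", "CRSwNP"],
        "macrolide": ["0", "1"],
        "bec": ["<150", "150-300", ">=300"],
        "fev1pp": ["<60", "60-80", ">=80"],
        "feno": ["<25", "25-50", ">=50"],
        "ige": ["<150", "150-600", ">=600"],
        "prior_exac": ["0", "1", "2"],
        "future_exac": ["0", "1", "2"],
    }
    parents: dict[str, tuple[str, ...]] = {
        "age": (), "sex": (), "ige": (),
        "crs": ("age", "sex"),
        "macrolide": ("age",),
        "bec": ("crs",),
        "fev1pp": ("crs",),
        "feno": ("crs", "fev1pp", "bec"),
        "prior_exac": ("bec", "feno", "fev1pp"),
        "future_exac": ("prior_exac", "bec", "feno", "fev1pp", "macrolide"),
    }
    if macrolide_to_prior:
        parents["prior_exac"] = parents["prior_exac"] + ("macrolide",)

    cpts: dict[str, np.ndarray] = {}
    # roots
    p_age = _EMISSIONS["age"].band_probs()
    cpts["age"] = p_age
    cpts["sex"] = np.array([_TARGETS["female"], 1 - _TARGETS["female"]])
    cpts["ige"] = _EMISSIONS["ige"].band_probs()

    w_age_sex = p_age[:, None] * cpts["sex"][None, :]
    # CRS: two-stage logistic (any CRS, then with-NP among CRS)
    eta_any = (np.asarray(_EFFECTS["crs_any_age"])[:, None]
               + np.asarray(_EFFECTS["crs_any_sex"])[None, :])
    b_any = _bisect(lambda b: float(
        np.sum(w_age_sex * _sigmoid(b + eta_any))) - _TARGETS["crs_any"])
    p_any = _sigmoid(b_any + eta_any)
    eta_wnp = (np.asarray(_EFFECTS["crs_wnp_age"])[:, None]
               + np.asarray(_EFFECTS["crs_wnp_sex"])[None, :])
    b_wnp = _bisect(lambda b: float(
        np.sum(w_age_sex * p_any * _sigmoid(b + eta_wnp))) - _TARGETS["crs_wnp"])
    p_wnp = _sigmoid(b_wnp + eta_wnp)
    cpts["crs"] = np.stack(
        [1 - p_any, p_any * (1 - p_wnp), p_any * p_wnp], axis=-1)

    cpts["macrolide"] = _binary_logit_cpt(
        np.asarray(_EFFECTS["macrolide_age"]), p_age, _TARGETS["macrolide"])

    p_crs = np.einsum("as,asc->c", w_age_sex, cpts["crs"])
    bec_bands = _EMISSIONS["bec"].band_probs()
    cpts["bec"] = _ordered_logit_cpt(
        np.asarray(_EFFECTS["bec_crs"]), p_crs,
        (float(bec_bands[0]), float(bec_bands[:2].sum())))
    fev_bands = _EMISSIONS["fev1pp"].band_probs()
    cpts["fev1pp"] = _ordered_logit_cpt(
        np.asarray(_EFFECTS["fev_crs"]), p_crs,
        (float(fev_bands[0]), float(fev_bands[:2].sum())))

    # exact joint of (crs, fev, bec): fev ⫫ bec | crs
    w_cfb = (p_crs[:, None, None] * cpts["fev1pp"][:, :, None]
             * cpts["bec"][:, None, :])
    eta_feno = (np.asarray(_EFFECTS["feno_crs"])[:, None, None]
                + np.asarray(_EFFECTS["feno_fev"])[None, :, None]
                + np.asarray(_EFFECTS["feno_bec"])[None, None, :])
    feno_bands = _EMISSIONS["feno"].band_probs()
    cpts["feno"] = _ordered_logit_cpt(
        eta_feno, w_cfb, (float(feno_bands[0]), float(feno_bands[:2].sum())))

    # joint over (bec, feno, fev1pp) for prior calibration
    w_bff = np.einsum("cfb,cfbo->bof", w_cfb, cpts["feno"])
    eta_prior = (np.asarray(_EFFECTS["prior_bec"])[:, None, None]
                 + np.asarray(_EFFECTS["prior_feno"])[None, :, None]
                 + np.asarray(_EFFECTS["prior_fev"])[None, None, :])
    if macrolide_to_prior:
        p_mac = np.einsum("a,am->m", p_age, cpts["macrolide"])
        eta_prior = eta_prior[..., None] + np.array([0.0, 0.6])[None, None, None, :]
        w_prior = w_bff[..., None] * p_mac[None, None, None, :]
    else:
        w_prior = w_bff
    cpt_prior, _ = _nb_count_cpt(eta_prior, w_prior, _TARGETS["prior_mean"])
    cpts["prior_exac"] = cpt_prior

    # joint over (prior, bec, feno, fev1pp, macrolide)
    p_mac = np.einsum("a,am->m", p_age, cpts["macrolide"])
    if macrolide_to_prior:
        w_pbffm = np.einsum("bofm,bofmp->pbofm", w_prior, cpt_prior)
    else:
        w_pbff = np.einsum("bof,bofp->pbof", w_bff, cpt_prior)
        w_pbffm = w_pbff[..., None] * p_mac[None, None, None, None, :]
    eta_future = (np.asarray(_EFFECTS["future_prior"])[:, None, None, None, None]
                  + np.asarray(_EFFECTS["future_bec"])[None, :, None, None, None]
                  + np.asarray(_EFFECTS["future_feno"])[None, None, :, None, None]
                  + np.asarray(_EFFECTS["future_fev"])[None, None, None, :, None]
                  + np.asarray(_EFFECTS["future_macrolide"])[None, None, None, None, :])
    cpt_future, future_rates = _nb_count_cpt(
        eta_future, w_pbffm, _TARGETS["future_mean"], country.multipliers,
        cap=2.0)
    cpts["future_exac"] = cpt_future

    if name == "extended15":
        extra = {
            "er_visits": (("prior_exac",), ["0", "1", "2"]),
            "invasive_ventilation": (("prior_exac",), ["0", "1"]),
            "lama": (("fev1pp",), ["0", "1"]),
            "anxiety": (("prior_exac",), ["0", "1"]),
            "eczema": (("crs",), ["0", "1"]),
        }
        p_prior = np.einsum("bof,bofp->p", w_bff, cpt_prior)
        p_fev = np.einsum("c,cf->f", p_crs, cpts["fev1pp"])
        nodes = nodes + list(extra)
        for node, (ps, lv) in extra.items():
            levels[node] = lv
            parents[node] = ps
            if node == "er_visits":
                cpt, _ = _nb_count_cpt(np.asarray(_EFFECTS["er_prior"]),
                                       p_prior, _TARGETS["er_mean"])
                cpts[node] = cpt
            elif node == "invasive_ventilation":
                cpts[node] = _binary_logit_cpt(
                    np.asarray(_EFFECTS["invvent_prior"]), p_prior,
                    _TARGETS["invasive_ventilation"])
            elif node == "lama":
                cpts[node] = _binary_logit_cpt(
                    np.asarray(_EFFECTS["lama_fev"]), p_fev, _TARGETS["lama"])
            elif node == "anxiety":
                cpts[node] = _binary_logit_cpt(
                    np.asarray(_EFFECTS["anxiety_prior"]), p_prior,
                    _TARGETS["anxiety"])
            elif node == "eczema":
                cpts[node] = _binary_logit_cpt(
                    np.asarray(_EFFECTS["eczema_crs"]), p_crs,
                    _TARGETS["eczema"])

    return GroundTruthSpec(
        nodes=nodes, levels=levels, parents=parents, cpts=cpts,
        emissions=dict(_EMISSIONS), country=country,
        missingness=list(_DEFAULT_MISSINGNESS), name=name,
        latent_future_rate=future_rates,
    )


def make_ground_truth_network(preset: str | GroundTruthSpec = "core9",
                              macrolide_to_prior: bool = False
                              ) -> GroundTruthSpec:
    """Return a validated ground-truth spec.

    ``core9`` is the 10-node default pathway (9 pathway predictors plus the
    12-month outcome; IgE is present but unconnected, reflecting its absence
    from the essential pathway).  ``extended15`` adds the downstream
    consequence nodes (ER visits, invasive ventilation, LAMA, anxiety,
    eczema).  A :class:`GroundTruthSpec` instance is validated and returned
    unchanged.  ``macrolide_to_prior`` adds the optional Macrolide→PriorExac
    arc.
    """
    if isinstance(preset, GroundTruthSpec):
        preset.validate()
        return preset
    if preset not in ("core9", "extended15"):
        raise ValueError(f"unknown preset {preset!r}")
    return _build_preset(preset, macrolide_to_prior=macrolide_to_prior)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_discrete(cpt: np.ndarray, parent_codes: list[np.ndarray],
                     rng: np.random.Generator, n: int) -> np.ndarray:
    r = cpt.shape[-1]
    flat = cpt.reshape(-1, r)
    if parent_codes:
        cards = cpt.shape[:-1]
        idx = np.zeros(n, dtype=np.int64)
        for card, code in zip(cards, parent_codes):
            idx = idx * card + code
    else:
        idx = np.zeros(n, dtype=np.int64)
    cum = np.cumsum(flat, axis=1)
    u = rng.random(n)
    lev = (cum[idx] < u[:, None]).sum(axis=1)
    return np.minimum(lev, r - 1).astype(np.int64)


def sample_cohort(spec: GroundTruthSpec, n: int, seed: int,
                  return_bands: bool = False) -> pd.DataFrame:
    """Ancestral sampling of a registry-like cohort table.

    Bands are drawn in topological order (parents before children), then
    continuous measurements are emitted within the sampled band, the country
    label is attached and the outcome is redrawn under the country's rate
    multiplier.  Reproducible given ``(spec, n, seed)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_bands, rng_emit, rng_country, rng_noise = rngs

    bands: dict[str, np.ndarray] = {}
    for node in spec.nodes:
        if node == "future_exac":
            continue          # drawn below under the country rate multiplier
        ps = spec.parents.get(node, ())
        bands[node] = _sample_discrete(
            spec.cpts[node], [bands[p] for p in ps], rng_bands, n)

    # country and country-adjusted outcome
    k = spec.country.k
    country_idx = rng_country.integers(0, k, size=n)
    mult = np.asarray(spec.country.multipliers)[country_idx]
    fut_parents = spec.parents["future_exac"]
    lam = _future_rate(spec, {p: bands[p] for p in fut_parents})
    bands["future_exac"] = _sample_nb_levels(lam * mult, rng_bands)

    out: dict[str, object] = {"patient_id": np.arange(1, n + 1)}
    for col in ["age", "bec", "feno", "fev1pp", "ige"]:
        out[col] = spec.emissions[col].sample(bands[col], rng_emit)
    out["sex"] = np.asarray(spec.levels["sex"], dtype=object)[bands["sex"]]
    out["crs"] = np.asarray(spec.levels["crs"], dtype=object)[bands["crs"]]
    out["macrolide"] = bands["macrolide"]
    out["prior_exac"] = bands["prior_exac"]
    out["future_exac"] = bands["future_exac"]
    out["country"] = np.asarray(spec.country.labels, dtype=object)[country_idx]

    # columns outside the pathway network: independent registry-style noise
    out["fev1_reversibility"] = np.maximum(
        rng_noise.normal(5.5, 9.1, size=n), -20.0)
    for col, pcol in [("er_visits", None), ("invasive_ventilation", None),
                      ("lama", None), ("anxiety", None), ("eczema", None)]:
        if col in spec.nodes:
            out[col] = bands[col]
        elif col == "er_visits":
            lam_er = np.full(n, _TARGETS["er_mean"])
            out[col] = _sample_nb_levels(lam_er, rng_noise)
        else:
            out[col] = (rng_noise.random(n) < _TARGETS[col]).astype(np.int64)

    df = pd.DataFrame(out)[COHORT_COLUMNS]
    if return_bands:
        for nname in spec.nodes:
            df[f"_band_{nname}"] = bands[nname]
    return df


def _future_rate(spec: GroundTruthSpec, parent_bands: dict[str, np.ndarray]
                 ) -> np.ndarray:
    """Latent (multiplier-1) outcome rate per row given parent bands."""
    cpt = spec.cpts["future_exac"]
    ps = spec.parents["future_exac"]
    idx = np.zeros_like(parent_bands[ps[0]])
    for j, p in enumerate(ps):
        idx = idx * cpt.shape[j] + parent_bands[p]
    if spec.latent_future_rate is not None:
        return spec.latent_future_rate.reshape(-1)[idx]
    # custom spec without a stored rate: invert the NB zero probability
    rows = cpt.reshape(-1, 3)[idx]
    p0 = np.clip(rows[:, 0], 1e-12, 1 - 1e-12)
    lam = _NB_SIZE * (p0 ** (-1.0 / _NB_SIZE) - 1.0)
    return lam / float(np.mean(spec.country.multipliers))


def _sample_nb_levels(lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = _NB_SIZE / (_NB_SIZE + np.asarray(lam, dtype=float))
    counts = rng.negative_binomial(_NB_SIZE, p)
    return np.minimum(counts, 2).astype(np.int64)


# ---------------------------------------------------------------------------
# missingness & country
# ---------------------------------------------------------------------------

def inject_missingness(cohort: pd.DataFrame,
                       spec: GroundTruthSpec | list[MissingnessRule],
                       seed: int) -> pd.DataFrame:
    """Mask cells per the missingness rules; the outcome is never masked."""
    rules = spec.missingness if isinstance(spec, GroundTruthSpec) else list(spec)
    out = cohort.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    masked_cols = {r.column for r in rules if r.rate > 0}
    for r in rules:
        r.validate()
        if r.mechanism == "mar" and r.driver in masked_cols:
            raise ValueError(
                f"MAR driver {r.driver!r} is itself targeted for masking")
        if r.column == "future_exac":
            raise ValueError("outcome column must stay observed")
        if r.rate == 0:
            continue
        n = len(out)
        if r.mechanism == "mcar":
            mask = rng.random(n) < r.rate
        else:
            if r.driver not in out.columns:
                raise ValueError(f"MAR driver {r.driver!r} missing from cohort")
            drv = out[r.driver]
            if drv.isna().any():
                raise ValueError(f"MAR driver {r.driver!r} must be fully observed")
            codes = pd.Categorical(drv).codes.astype(float)
            logodds = np.log(r.odds) * codes
            base = _bisect(lambda b: float(
                np.mean(_sigmoid(b + logodds))) - r.rate)
            mask = rng.random(n) < _sigmoid(base + logodds)
        out.loc[mask, r.column] = np.nan
    return out


def assign_country(cohort: pd.DataFrame, spec: GroundTruthSpec,
                   k_countries: int, effect_sd: float, seed: int
                   ) -> pd.DataFrame:
    """Relabel countries and redraw the outcome under per-country rate shifts.

    Each patient gets one of ``k_countries`` labels; the outcome-generating
    negative-binomial rate is multiplied by a per-country factor with
    log-standard-deviation ``effect_sd`` (draw is seeded).
    """
    if k_countries < 2:
        raise ValueError("need at least 2 countries")
    ss = np.random.SeedSequence(seed)
    rng_lab, rng_mult, rng_out = (np.random.default_rng(s) for s in ss.spawn(3))
    n = len(cohort)
    out = cohort.copy()
    idx = rng_lab.integers(0, k_countries, size=n)
    out["country"] = np.asarray(
        [f"C{i + 1:02d}" for i in range(k_countries)], dtype=object)[idx]
    mult = np.exp(rng_mult.normal(0.0, effect_sd, size=k_countries))[idx] \
        if effect_sd > 0 else np.ones(n)
    parent_bands = {}
    for p in spec.parents["future_exac"]:
        if p in spec.emissions:
            parent_bands[p] = spec.band_of(p, out[p].to_numpy())
        else:
            cats = [str(l) for l in spec.levels[p]]
            parent_bands[p] = pd.Categorical(
                out[p].astype(str), categories=cats).codes.astype(np.int64)
    lam = _future_rate(spec, parent_bands)
    out["future_exac"] = _sample_nb_levels(lam * mult, rng_out)
    return out
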