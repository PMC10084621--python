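"""Synthetic design, phenotype, count and ontology generators with known
ground truth.

The generators emulate a growth-chamber common-garden experiment: larvae from
2 latitudes x 2 ponds per latitude x 10 maternal lines per pond are reared
factorially at 2 temperatures x 2 predator-cue treatments, with 1-2 larvae
phenotyped per family-by-treatment container (the second with probability
``p_second_larva``; the default 0.7 gives an expected 272 phenotyped
individuals). Two phenotype models are provided:

* :func:`simulate_phenotypes` draws traits from an effects model (intercepts,
  treatment main effects and interactions, pond/family random effects) with
  Gaussian traits on their model scale and Poisson development time on the
  log scale.
* :func:`simulate_planted_axes` plants an exact canonical-correlation
  structure: whitened environment axes u_k, latent trait axes
  t_k = rho_k u_k + sqrt(1 - rho_k^2) eps_k, and traits built so the
  analysis-scale trait matrix carries each t_k linearly. The population
  canonical correlations between traits and environment are then exactly
  ``rho``.

Counts are negative binomial, count_gi ~ NB(mean = L_i exp(b_g + gamma_g z_i),
dispersion phi_g), where z_i is the individual's latent axis score — a blend
of the environment axis u_k and the trait axis t_k, which is what makes the
CCp- and CCe-tail DE lists overlap for planted genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import CountsMatrix, OntologyGraph, ValidationError

# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class DesignConfig:
    n_latitudes: int = 2
    ponds_per_latitude: int = 2
    families_per_pond: int = 10
    temperatures: tuple[int, int] = (20, 24)
    predator_levels: tuple[str, str] = ("absent", "present")
    p_second_larva: float = 0.7     # expected N = 160 * (1 + 0.7) = 272
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_second_larva <= 1.0):
            raise ValueError("p_second_larva must be in [0, 1]")
        if min(self.n_latitudes, self.ponds_per_latitude, self.families_per_pond) < 1:
            raise ValueError("all design counts must be >= 1")


_LAT_NAMES = ("high", "central")


def generate_design(cfg: DesignConfig | None = None) -> pd.DataFrame:
    """One row per phenotyped larva; every family appears in all four
    treatment combinations; deterministic given ``cfg.seed``."""
    cfg = cfg or DesignConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for li in range(cfg.n_latitudes):
        lat = _LAT_NAMES[li % 2]
        for pi in range(cfg.ponds_per_latitude):
            pond = f"{lat[0].upper()}{pi + 1}"
            for fi in range(cfg.families_per_pond):
                fam = f"{pond}_F{fi + 1:02d}"
                for temp in cfg.temperatures:
                    for pred in cfg.predator_levels:
                        n_larvae = 1 + int(rng.random() < cfg.p_second_larva)
                        for _ in range(n_larvae):
                            rows.append((pond, fam, lat, temp, pred))
    df = pd.DataFrame(rows, columns=["pond_id", "maternal_line", "latitude",
                                     "temperature", "predator"])
    df.insert(0, "individual_id", [f"ind{i + 1:04d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# effects-model phenotypes
# ---------------------------------------------------------------------------

_EFFECT_KEYS = ("latitude", "temperature", "predator",
                "latitude:temperature", "latitude:predator",
                "temperature:predator", "latitude:temperature:predator")


@dataclass
class TraitEffects:
    """Effect structure for the four measured traits.

    Intercepts and effects are on the model scale: natural (mg) for mass,
    log for head_width and wing_pad (mm), log for dev_time (days; Poisson
    outcome). ``effects[trait]`` maps any of latitude / temperature /
    predator / their interactions to a coefficient (missing keys are 0);
    indicators are central=1, 24 C=1, present=1.
    """

    intercepts: dict[str, float] = field(default_factory=lambda: {
        "mass": 5.0, "head_width": 0.0, "wing_pad": 0.7, "dev_time": 3.0})
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    pond_sd: dict[str, float] = field(default_factory=lambda: {
        "mass": 0.15, "head_width": 0.02, "wing_pad": 0.02, "dev_time": 0.03})
    family_sd: dict[str, float] = field(default_factory=lambda: {
        "mass": 0.25, "head_width": 0.03, "wing_pad": 0.03, "dev_time": 0.04})
    resid_sd: dict[str, float] = field(default_factory=lambda: {
        "mass": 0.6, "head_width": 0.08, "wing_pad": 0.10})
    dev_time_noise: bool = True  # False suppresses the Poisson draw (mean rounded)

    def __post_init__(self) -> None:
        for d in (self.pond_sd, self.family_sd, self.resid_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be >= 0")


def _linear_predictor(design: pd.DataFrame, trait: str, eff: TraitEffects) -> np.ndarray:
    lat = (design["latitude"] == "central").to_numpy(float)
    temp = (design["temperature"] == 24).to_numpy(float)
    pred = (design["predator"] == "present").to_numpy(float)
    terms = {
        "latitude": lat, "temperature": temp, "predator": pred,
        "latitude:temperature": lat * temp, "latitude:predator": lat * pred,
        "temperature:predator": temp * pred,
        "latitude:temperature:predator": lat * temp * pred,
    }
    eta = np.full(len(design), eff.intercepts[trait])
    for key, coef in eff.effects.get(trait, {}).items():
        if key not in terms:
            raise ValueError(f"unknown effect term {key!r}")
        eta += coef * terms[key]
    return eta


def simulate_phenotypes(design: pd.DataFrame, effects: TraitEffects | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Draw mass/head_width/wing_pad (Gaussian on model scale) and dev_time
    (Poisson, log link) on top of a design table; deterministic given seed."""
    effects = effects or TraitEffects()
    rng = np.random.default_rng(seed)
    out = design.copy()
    ponds = design["pond_id"].unique()
    fams = design["maternal_line"].unique()
    for trait in ("mass", "head_width", "wing_pad", "dev_time"):
        eta = _linear_predictor(design, trait, effects)
        pond_fx = dict(zip(ponds, rng.normal(0, effects.pond_sd.get(trait, 0), len(ponds))))
        fam_fx = dict(zip(fams, rng.normal(0, effects.family_sd.get(trait, 0), len(fams))))
        eta = eta + design["pond_id"].map(pond_fx).to_numpy() \
                  + design["maternal_line"].map(fam_fx).to_numpy()
        if trait == "dev_time":
            mu = np.exp(eta)
            if effects.dev_time_noise:
                vals = rng.poisson(mu).astype(float)
                vals = np.maximum(vals, 1)
            else:
                vals = np.round(mu)
        else:
            sd = effects.resid_sd.get(trait, 0)
            vals = eta + rng.normal(0, sd, len(design))
            if trait in ("head_width", "wing_pad"):
                vals = np.exp(vals)
            # natural-scale traits must stay positive; resample a bounded
            # number of times before giving up
            for _ in range(100):
                bad = vals <= 0
                if not bad.any():
                    break
                vals[bad] = eta[bad] + rng.normal(0, sd, int(bad.sum()))
            if (vals <= 0).any():
                raise ValidationError(
                    f"simulated {trait} stayed non-positive after 100 resamples; "
                    "check intercepts and residual sd")
        out[trait] = vals
    out["dev_time"] = out["dev_time"].astype(int)
    return out


# ---------------------------------------------------------------------------
# planted canonical-correlation phenotypes
# ---------------------------------------------------------------------------

def _whiten_environment(design: pd.DataFrame) -> np.ndarray:
    """Empirically whitened environment axes (unit variance, uncorrelated),
    deterministic functions of the coded design."""
    Y = np.column_stack([
        (design["latitude"] == "central").to_numpy(float),
        (design["temperature"] == 24).to_numpy(float),
        (design["predator"] == "present").to_numpy(float),
    ])
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    C = Ys.T @ Ys / (len(Y) - 1)
    vals, vecs = np.linalg.eigh(C)
    return Ys @ (vecs @ np.diag(vals ** -0.5) @ vecs.T)


def simulate_planted_axes(
    design: pd.DataFrame,
    rho: tuple[float, float, float] = (0.85, 0.5, 0.25),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotypes whose analysis-scale traits have planted canonical
    correlations ``rho`` with the coded environment.

    Latent construction: with whitened environment axes u_k,
    t_k = rho_k u_k + sqrt(1 - rho_k^2) eps_k. The analysis-scale carriers
    are dev_time (-t1, days around 20), arcsin GRM (a 0.8 t1 + 0.6 noise
    blend), log head width (t2) and log wing pad (t3); mass = GRM x dev_time
    is derived so the growth rate round-trips exactly through the pipeline's
    mass / dev_time derivation.

    Returns (phenotype table, axes table). The axes table holds u_k, t_k and
    the blended expression axes z_k = (u_k + t_k) / sqrt(2 (1 + rho_k)),
    each unit-variance and tied to both the environment and the traits.
    rho = (0, 0, 0) gives a fully null phenotype set.
    """
    rng = np.random.default_rng(seed)
    n = len(design)
    rho_arr = np.asarray(rho, dtype=float)
    if np.any((rho_arr < 0) | (rho_arr >= 1)):
        raise ValueError("planted correlations must lie in [0, 1)")
    U = _whiten_environment(design)
    eps = rng.standard_normal((n, 3))
    T = rho_arr * U + np.sqrt(1 - rho_arr**2) * eps
    noise = rng.standard_normal((n, 2))

    dev_time = np.round(20.0 + 3.0 * (-T[:, 0])).clip(min=5).astype(int)
    arcsin_grm = 0.2527 + 0.05 * (0.8 * T[:, 0] + 0.6 * noise[:, 0])
    arcsin_grm = arcsin_grm.clip(0.02, np.pi / 2 - 0.02)
    grm = np.sin(arcsin_grm)
    head = np.exp(0.0 + 0.08 * T[:, 1])
    wing = np.exp(0.7 + 0.10 * T[:, 2])
    mass = grm * dev_time

    pheno = design.copy()
    pheno["mass"] = mass
    pheno["head_width"] = head
    pheno["wing_pad"] = wing
    pheno["dev_time"] = dev_time

    Z = (U + T) / np.sqrt(2.0 * (1.0 + rho_arr))
    axes = pd.DataFrame(
        np.column_stack([U, T, Z]),
        columns=[f"u{k}" for k in (1, 2, 3)] + [f"t{k}" for k in (1, 2, 3)]
                + [f"z{k}" for k in (1, 2, 3)],
        index=pd.Index(design["individual_id"], name="individual_id"),
    )
    return pheno, axes


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTruth:
    """Planted generative parameters for the count matrix."""

    n_genes: int
    baseline_logmean: np.ndarray      # log relative abundance, sums to ~1 after exp
    dispersion: np.ndarray            # phi_g > 0
    gamma: np.ndarray                 # genes x axes, natural-log FC per unit z
    planted_up: dict[int, list[str]]  # axis (1-based) -> gene ids
    planted_down: dict[int, list[str]]
    lib_median: float = 1e6
    lib_sigma: float = 0.3

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(self.n_genes)]

    def __post_init__(self) -> None:
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersions must be positive")
        for ax in self.planted_up:
            if set(self.planted_up[ax]) & set(self.planted_down.get(ax, [])):
                raise ValueError("a gene cannot be planted up and down on one axis")


def make_expression_truth(
    n_genes: int = 2000,
    n_axes: int = 3,
    planted: dict[int, int] | None = None,
    effect: float = 1.5,
    dispersion_median: float = 0.1,
    dispersion_sigma: float = 0.5,
    lib_median: float = 1e6,
    lib_sigma: float = 0.3,
    seed: int = 0,
) -> ExpressionTruth:
    """Draw per-gene baselines and dispersions and plant effect genes.

    ``planted`` maps axis (1-based) to the number of affected genes (half up,
    half down, effect size +/- ``effect`` natural-log units per unit z).
    Dispersions are log-normal (median ``dispersion_median``, sigma
    ``dispersion_sigma``); baseline abundances are log-normal.
    """
    rng = np.random.default_rng(seed)
    planted = planted or {}
    base = rng.normal(0.0, 1.2, n_genes)
    base = base - np.log(np.exp(base).sum())      # relative abundances sum to 1
    phi = np.exp(rng.normal(np.log(dispersion_median), dispersion_sigma, n_genes))
    gamma = np.zeros((n_genes, n_axes))
    ids = [f"gene{i:04d}" for i in range(n_genes)]
    up: dict[int, list[str]] = {}
    down: dict[int, list[str]] = {}
    used: set[int] = set()
    for axis, count in sorted(planted.items()):
        free = np.array(sorted(set(range(n_genes)) - used))
        chosen = rng.choice(free, size=count, replace=False)
        used |= set(int(i) for i in chosen)
        half = count // 2
        gamma[chosen[:half], axis - 1] = effect
        gamma[chosen[half:], axis - 1] = -effect
        up[axis] = [ids[i] for i in sorted(chosen[:half])]
        down[axis] = [ids[i] for i in sorted(chosen[half:])]
    return ExpressionTruth(n_genes=n_genes, baseline_logmean=base, dispersion=phi,
                           gamma=gamma, planted_up=up, planted_down=down,
                           lib_median=lib_median, lib_sigma=lib_sigma)


def simulate_counts(sample_ids: list[str], z: np.ndarray | pd.DataFrame,
                    truth: ExpressionTruth, seed: int = 0) -> CountsMatrix:
    """NB counts: count_gi ~ NB(mean = L_i exp(b_g + gamma_g . z_i), phi_g).

    ``z`` is samples x axes (only the first ``truth.gamma.shape[1]`` columns
    are used); library sizes are log-normal. Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    zarr = np.asarray(z, dtype=float)
    if zarr.ndim == 1:
        zarr = zarr[:, None]
    n = len(sample_ids)
    if zarr.shape[0] != n:
        raise ValidationError("z must have one row per sample")
    zarr = zarr[:, :truth.gamma.shape[1]]
    lib = np.exp(rng.normal(np.log(truth.lib_median), truth.lib_sigma, n))
    logmean = (truth.baseline_logmean[:, None]
               + truth.gamma[:, :zarr.shape[1]] @ zarr.T
               + np.log(lib)[None, :])
    mean = np.exp(logmean)
    r = 1.0 / truth.dispersion[:, None]
    p = r / (r + mean)
    counts = rng.negative_binomial(np.broadcast_to(r, mean.shape), p)
    df = pd.DataFrame(counts, index=pd.Index(truth.gene_ids, name="Geneid"),
                      columns=list(sample_ids))
    chrom = pd.Series("1", index=df.index, name="Chr")  # all autosomal
    return CountsMatrix(counts=df.astype(np.int64), gene_chrom=chrom)


# ---------------------------------------------------------------------------
# ontology fixture
# ---------------------------------------------------------------------------

_NS_SPLIT = {"biological_process": 0.5, "cellular_component": 0.25,
             "molecular_function": 0.25}


def generate_ontology_fixture(
    n_terms: int = 30, n_genes: int = 50, seed: int = 0
) -> tuple[OntologyGraph, dict[str, set[str]], pd.DataFrame]:
    """Random is_a DAG per namespace, a gene->term annotation, and a reference
    insect table with controlled transfer-rule cases.

    The reference table contains, among filler rows, three constructed gene
    names: ``consensus3`` (identical GO set in 3 species -> transferable),
    ``pair2`` (identical set in only 2 species -> not transferable) and
    ``majority4`` (4 species, one with a differing set -> the 3-species
    consensus still qualifies).
    """
    if n_terms < 5:
        raise ValueError("need at least 5 terms")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    terms: dict[str, tuple[str, str]] = {}
    counter = 0
    ns_terms: dict[str, list[str]] = {}
    for ns, frac in _NS_SPLIT.items():
        k = max(2, int(round(n_terms * frac)))
        ids = []
        for j in range(k):
            tid = f"GO:{counter:07d}"
            counter += 1
            terms[tid] = (f"{ns} term {j}", ns)
            g.add_node(tid)
            if ids:  # non-root: 1-2 parents among earlier terms of the namespace
                for parent in rng.choice(ids, size=min(len(ids), int(rng.integers(1, 3))),
                                         replace=False):
                    g.add_edge(tid, parent)
            ids.append(tid)
        ns_terms[ns] = ids
    onto = OntologyGraph(graph=g, terms=terms)

    all_terms = list(terms)
    ann: dict[str, set[str]] = {}
    for i in range(n_genes):
        k = int(rng.integers(1, 5))
        ann[f"gene{i:04d}"] = set(rng.choice(all_terms, size=k, replace=False))

    set_a = sorted(rng.choice(all_terms, size=2, replace=False))
    set_b = sorted(rng.choice(all_terms, size=3, replace=False))
    rows = []
    species = [f"Insecta sp{j}" for j in range(1, 7)]
    for sp in species[:3]:
        rows.append((sp, "consensus3", "conserved kinase", ";".join(set_a)))
    for sp in species[:2]:
        rows.append((sp, "pair2", "orphan receptor", ";".join(set_a)))
    for sp in species[:3]:
        rows.append((sp, "majority4", "consensus enzyme", ";".join(set_b)))
    rows.append((species[3], "majority4", "consensus enzyme", ";".join(set_a)))
    for i in range(10):  # filler, one species each
        t = sorted(rng.choice(all_terms, size=2, replace=False))
        rows.append((species[int(rng.integers(0, 6))], f"filler{i}", "misc", ";".join(t)))
    ref = pd.DataFrame(rows, columns=["species", "gene_name", "function", "go_terms"])
    ref["go_terms"] = [frozenset(s.split(";")) for s in ref["go_terms"]]
    return onto, ann, ref
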