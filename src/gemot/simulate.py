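"""Synthetic benchmark generators with ground-truth labels.

Three simulators of increasing scope, all linear-Gaussian over a biallelic
panel of homozygous individuals (genotypes are Bernoulli(0.5)):

* triplets -- independent (v, g, p) triples drawn from the five causal
  wirings M1-M5, used to benchmark the causality test itself;
* sub-networks -- one variant, m causal transcripts driving k shared traits,
  plus a reactive transcript/trait pair and an independent pair, mimicking a
  tripartite module handed to stage III;
* networks -- several sub-networks embedded in a background of independent
  variants, standard-normal traits, and covariance-structured transcripts
  coupled to the sub-networks, exercising the whole pipeline.

Every structural edge a_i -> a_j with coefficient beta contributes
beta * a_i; each equation carries a single Gaussian residual with
sd = noise_level * beta (the relative-noise convention), and intercepts are
zero throughout.  Strong edges (v -> g, v -> p) use beta = 1.5 and weak edges
(g -> p, p -> g) use beta = 0.6 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from gemot.bicluster import BipartiteModule
from gemot.rng import derive_seeds
from gemot.data import AlignedDataset, LabeledMatrix, VariantTable
from gemot.transcripts import TripartiteModule

BROAD_SENSE_POSITIVE = frozenset({"M1", "M4"})


@dataclass
class TripletSpec:
    n_individuals: int = 100
    per_model_count: int = 250
    alpha: float = 0.5
    lambda_: float = 4.0
    sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.per_model_count < 1 or self.n_individuals < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class TripletCollection:
    """Stacked triplets: row i of v/g/p is one triplet; labels[i] is its model."""

    v: np.ndarray
    g: np.ndarray
    p: np.ndarray
    labels: list[str]


@dataclass
class SubNetworkSpec:
    net_kind: str = "Net-1"
    k: int = 5  # causal traits; total traits = k + 2
    m: int = 3  # causal transcripts
    noise_level: float = 0.5
    beta_strong: float = 1.5
    beta_weak: float = 0.6
    n_individuals: int = 100
    n_subnetworks: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_level <= 0:
            raise ValueError("noise_level must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.net_kind not in ("Net-1", "Net-2", "Net-3"):
            raise ValueError("net_kind must be one of Net-1, Net-2, Net-3")


@dataclass
class NetworkSpec:
    n_variants: int = 100
    n_traits: int = 100
    n_transcripts: int = 200
    n_subnetworks: int = 5
    c: float = 1.0
    background_cov: np.ndarray | None = None
    sub_spec: SubNetworkSpec = field(default_factory=SubNetworkSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_variants, self.n_traits, self.n_transcripts, self.n_subnetworks) < 1:
            raise ValueError("dimensions must be positive")
        if self.c < 0:
            raise ValueError("c must be >= 0")


@dataclass
class SyntheticTruth:
    """Class labels partitioning all traits and transcripts, plus membership.

    trait_class / transcript_class values: causal_shared, reactive,
    independent, background.  subnetworks maps a sub-network id to its
    variant, full trait set P(s), causal trait subset P^C(s), and transcript
    sets G(s), G^C(s).
    """

    trait_class: dict[str, str]
    transcript_class: dict[str, str]
    subnetworks: dict[str, dict[str, object]]

    def causal_traits(self, sub_id: str) -> set[str]:
        return set(self.subnetworks[sub_id]["P_C"])

    def all_traits(self, sub_id: str) -> set[str]:
        return set(self.subnetworks[sub_id]["P"])


def _noise(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    return rng.normal(0.0, sd, size=size)


def simulate_triplets(spec: TripletSpec) -> tuple[TripletCollection, list[str]]:
    """Draw ``per_model_count`` triplets from each of M1-M5.

    Returns the collection and the broad-sense-positive model ids (M1, M4).
    """
    rng = np.random.default_rng(spec.seed)
    n, a, lam, s = spec.n_individuals, spec.alpha, spec.lambda_, spec.sigma
    vs, gs, ps, labels = [], [], [], []
    for model in ("M1", "M2", "M3", "M4", "M5"):
        for _ in range(spec.per_model_count):
            v = rng.binomial(1, 0.5, size=n).astype(float)
            if model == "M1":
                g = a * v + _noise(rng, s, n)
                p = lam * g + _noise(rng, s, n)
            elif model == "M2":
                g = a * v + _noise(rng, s, n)
                p = a * v + _noise(rng, s, n)
            elif model == "M3":
                p = a * v + _noise(rng, s, n)
                g = lam * p + _noise(rng, s, n)
            elif model == "M4":
                g = a * v + _noise(rng, s, n)
                p = a * v + lam * g + _noise(rng, s, n)
            else:  # M5
                p = a * v + _noise(rng, s, n)
                g = a * v + lam * p + _noise(rng, s, n)
            vs.append(v)
            gs.append(g)
            ps.append(p)
            labels.append(model)
    coll = TripletCollection(np.array(vs), np.array(gs), np.array(ps), labels)
    return coll, sorted(BROAD_SENSE_POSITIVE)


def _simulate_one_subnetwork(
    spec: SubNetworkSpec, rng: np.random.Generator, sub_id: str
) -> tuple[AlignedDataset, SyntheticTruth]:
    n = spec.n_individuals
    q, bs, bw = spec.noise_level, spec.beta_strong, spec.beta_weak
    v = rng.binomial(1, 0.5, size=n).astype(float)

    # causal transcripts and the k shared traits
    if spec.net_kind == "Net-3":
        # causal transcripts chained: v -> g1 -> g2 -> ... -> gm
        g_c = []
        parent = v
        beta = bs
        for _ in range(spec.m):
            g_i = beta * parent + _noise(rng, q * beta, n)
            g_c.append(g_i)
            parent, beta = g_i, bw
        g_c = np.array(g_c)
    else:
        g_c = np.array([bs * v + _noise(rng, q * bs, n) for _ in range(spec.m)])
    # each causal trait: one equation summing its m weak parent edges
    p_c = np.array(
        [bw * g_c.sum(axis=0) + _noise(rng, q * bw, n) for _ in range(spec.k)]
    )

    # reactive pair: v -> p_R -> g_R (duplicated transcript in Net-2)
    p_r = bs * v + _noise(rng, q * bs, n)
    g_r = [bw * p_r + _noise(rng, q * bw, n)]
    # independent pair: v -> p_I, v -> g_I
    p_i = bs * v + _noise(rng, q * bs, n)
    g_i = [bs * v + _noise(rng, q * bs, n)]
    if spec.net_kind == "Net-2":
        g_r.append(bw * p_r + _noise(rng, q * bw, n))
        g_i.append(bs * v + _noise(rng, q * bs, n))

    strains = [f"S{j:03d}" for j in range(n)]
    vid = f"{sub_id}_v"
    geno = VariantTable(
        [vid], ["1"], [1_000_000], LabeledMatrix(v[None, :], [vid], strains)
    )
    g_ids = (
        [f"{sub_id}_gC{i + 1}" for i in range(spec.m)]
        + [f"{sub_id}_gR{i + 1}" for i in range(len(g_r))]
        + [f"{sub_id}_gI{i + 1}" for i in range(len(g_i))]
    )
    expr = LabeledMatrix(np.vstack([g_c, np.array(g_r), np.array(g_i)]), g_ids, strains)
    t_ids = [f"{sub_id}_pC{j + 1}" for j in range(spec.k)] + [f"{sub_id}_pR1", f"{sub_id}_pI1"]
    traits = LabeledMatrix(np.vstack([p_c, p_r[None, :], p_i[None, :]]), t_ids, strains)
    ds = AlignedDataset(geno, expr, traits, strains)

    trait_class = {t: "causal_shared" for t in t_ids[: spec.k]}
    trait_class[f"{sub_id}_pR1"] = "reactive"
    trait_class[f"{sub_id}_pI1"] = "independent"
    transcript_class = {g: "causal_shared" for g in g_ids[: spec.m]}
    for g in g_ids[spec.m : spec.m + len(g_r)]:
        transcript_class[g] = "reactive"
    for g in g_ids[spec.m + len(g_r) :]:
        transcript_class[g] = "independent"
    truth = SyntheticTruth(
        trait_class,
        transcript_class,
        {
            sub_id: {
                "variant": vid,
                "P": list(t_ids),
                "P_C": list(t_ids[: spec.k]),
                "G": list(g_ids),
                "G_C": list(g_ids[: spec.m]),
            }
        },
    )
    return ds, truth


def simulate_subnetworks(spec: SubNetworkSpec) -> list[tuple[AlignedDataset, SyntheticTruth]]:
    """A collection of ``n_subnetworks`` independent co-mapped sub-networks."""
    rng = np.random.default_rng(spec.seed)
    return [
        _simulate_one_subnetwork(spec, rng, f"s{u:03d}")
        for u in range(spec.n_subnetworks)
    ]


def as_tripartite_module(ds: AlignedDataset) -> TripartiteModule:
    """View a simulated sub-network as the tripartite module stage III receives:
    its variant, all its traits, and all its transcripts as candidates."""
    vid = ds.genotypes.variant_ids[0]
    pos = ds.genotypes.position_bp[0]
    base = BipartiteModule(
        variant_ids=[vid],
        trait_ids=list(ds.traits.row_ids),
        interval=(ds.genotypes.chromosome[0], pos, pos),
        mean_weight=float("nan"),
    )
    return TripartiteModule(
        base=base,
        candidate_transcripts=list(ds.expression.row_ids),
        link_scores={g: float("nan") for g in ds.expression.row_ids},
    )


def synthesize_background_cov(
    n: int, n_blocks: int = 10, within_block_corr: float = 0.4, seed: int = 0
) -> np.ndarray:
    """A PSD block-plus-noise covariance mimicking gene-expression correlation
    structure: unit variances, ``within_block_corr`` within each block."""
    rng = np.random.default_rng(seed)
    blocks = rng.integers(0, n_blocks, size=n)
    same = blocks[:, None] == blocks[None, :]
    cov = np.where(same, within_block_corr, 0.0)
    np.fill_diagonal(cov, 1.0)
    return cov


def simulate_network(spec: NetworkSpec) -> tuple[AlignedDataset, SyntheticTruth]:
    """Embed sub-networks in a large network with covariance-structured background.

    Background transcripts x are multivariate normal with the requested
    covariance and are coupled to the sub-networks as z = x + c * y, where y
    is a uniformly chosen sub-network transcript per background transcript.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.sub_spec.n_individuals
    strains = [f"S{j:03d}" for j in range(n)]

    subs = []
    for u in range(spec.n_subnetworks):
        sub_seed = int(derive_seeds(spec.seed, spec.n_subnetworks)[u])
        one = replace(spec.sub_spec, n_subnetworks=1, seed=sub_seed)
        ds_u, truth_u = _simulate_one_subnetwork(one, np.random.default_rng(sub_seed), f"s{u:03d}")
        subs.append((ds_u, truth_u))

    n_sub_g = sum(ds.expression.shape[0] for ds, _ in subs)
    n_sub_t = sum(ds.traits.shape[0] for ds, _ in subs)
    n_bg_v = spec.n_variants - spec.n_subnetworks
    n_bg_g = spec.n_transcripts - n_sub_g
    n_bg_t = spec.n_traits - n_sub_t
    if min(n_bg_v, n_bg_g, n_bg_t) < 0:
        raise ValueError("sub-networks exceed the requested network dimensions")

    cov = spec.background_cov
    if cov is None:
        cov = synthesize_background_cov(n_bg_g, seed=spec.seed)
    else:
        cov = np.asarray(cov, dtype=float)
        if cov.shape[0] < n_bg_g:
            raise ValueError(f"background_cov must be at least {n_bg_g} x {n_bg_g}")
        cov = cov[:n_bg_g, :n_bg_g]
        eigmin = float(np.linalg.eigvalsh(cov).min())
        if eigmin < -1e-8:
            raise ValueError(
                "background_cov is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g}); project to the nearest PSD matrix first"
            )

    # genomic layout: planted variants spread evenly along one chromosome
    planted_pos = [
        int(round((u + 0.5) * spec.n_variants / spec.n_subnetworks))
        for u in range(spec.n_subnetworks)
    ]
    geno_rows = np.empty((spec.n_variants, n))
    variant_ids: list[str] = []
    chroms = ["1"] * spec.n_variants
    positions = [1_000_000 * (i + 1) for i in range(spec.n_variants)]
    if len(set(planted_pos)) < spec.n_subnetworks:
        planted_pos = list(range(spec.n_subnetworks))  # fallback for tiny grids
    planted_map = {pos: u for u, pos in enumerate(planted_pos)}
    bg_count = 0
    for i in range(spec.n_variants):
        if i in planted_map:
            u = planted_map[i]
            ds_u = subs[u][0]
            variant_ids.append(ds_u.genotypes.variant_ids[0])
            geno_rows[i] = ds_u.genotypes.genotypes.values[0]
        else:
            variant_ids.append(f"bgv{bg_count:03d}")
            geno_rows[i] = rng.binomial(1, 0.5, size=n).astype(float)
            bg_count += 1
    geno = VariantTable(
        variant_ids, chroms, positions, LabeledMatrix(geno_rows, variant_ids, strains)
    )

    # traits: planted first, then standard-normal background
    trait_rows = [ds.traits.values for ds, _ in subs]
    trait_ids = [t for ds, _ in subs for t in ds.traits.row_ids]
    bg_t = rng.standard_normal((n_bg_t, n))
    trait_ids += [f"bgp{j:03d}" for j in range(n_bg_t)]
    traits = LabeledMatrix(np.vstack([*trait_rows, bg_t]), trait_ids, strains)

    # transcripts: planted, then coupled background z = x + c * y_k
    sub_expr = np.vstack([ds.expression.values for ds, _ in subs])
    sub_g_ids = [g for ds, _ in subs for g in ds.expression.row_ids]
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_bg_g))
    x = (chol @ rng.standard_normal((n_bg_g, n)))
    pick = rng.integers(0, n_sub_g, size=n_bg_g)
    z = x + spec.c * sub_expr[pick]
    g_ids = sub_g_ids + [f"bgg{j:03d}" for j in range(n_bg_g)]
    expr = LabeledMatrix(np.vstack([sub_expr, z]), g_ids, strains)

    ds = AlignedDataset(geno, expr, traits, strains)
    trait_class = {}
    transcript_class = {}
    subnet_info = {}
    for ds_u, truth_u in subs:
        trait_class.update(truth_u.trait_class)
        transcript_class.update(truth_u.transcript_class)
        subnet_info.update(truth_u.subnetworks)
    for t in trait_ids:
        trait_class.setdefault(t, "background")
    for g in g_ids:
        transcript_class.setdefault(g, "background")
    return ds, SyntheticTruth(trait_class, transcript_class, subnet_info)
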