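"""Synthetic cohorts with a known latent branching trajectory.

The generator emulates the statistical structure the staging analysis
assumes about postmortem bulk RNA-seq cohorts: a few hundred samples whose
expression is driven by a latent position on a small planar tree, binary
case/control status and ordinal neuropathology-like scores that are
stochastically monotone in latent stage, designated cell-type marker and
"GWAS" gene sets with planted trajectories, and a minority of late-stage
control samples carrying a distinct upregulated gene cluster (the
"disease resistant" construction).  Ground truth (latent tree, per-sample
pseudotime and branch, gene programs, label-model parameters) is returned
alongside the data so recovery can be tested.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from ._graph import branch_decomposition, check_tree, vertex_distances
from ._utils import named_rng

__all__ = [
    "TrueTree",
    "SyntheticTruth",
    "GeneratedCohort",
    "generate_tree_topology",
    "sample_latent_positions",
    "generate_expression",
    "generate_clinical_labels",
    "plant_resistant_controls",
    "simulate_cohort",
]


@dataclass
class TrueTree:
    """The latent tree: 2-D vertex coordinates, edges with Euclidean
    lengths, a root vertex, and the topology label."""

    vertices: np.ndarray  # n_vertices x 2
    edges: list[tuple[int, int]]
    root_vertex: int
    topology_name: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        g = self.graph()
        check_tree(g)
        for i, j in self.edges:
            if g.edges[i, j]["length"] <= 0:
                raise ValueError(f"edge ({i},{j}) has non-positive length")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.vertices)))
        for i, j in self.edges:
            g.add_edge(i, j, length=float(np.linalg.norm(self.vertices[i] - self.vertices[j])))
        return g

    @property
    def total_length(self) -> float:
        return sum(self.graph().edges[e]["length"] for e in self.edges)


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the analysis must recover."""

    tree: TrueTree
    true_pseudotime: np.ndarray | None = None  # scaled to [0, 1]
    true_branch: np.ndarray | None = None  # 1-based branch ids
    gene_programs: dict[str, str] = field(default_factory=dict)
    label_params: dict = field(default_factory=dict)
    resistant_samples: list[str] = field(default_factory=list)
    resistant_genes: list[str] = field(default_factory=list)
    seed: int = 0


@dataclass
class GeneratedCohort:
    """Generated expression plus per-sample metadata and gene sets."""

    log_expression: np.ndarray  # genes x samples, log scale
    gene_ids: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame  # indexed by sample id
    counts: np.ndarray | None = None  # genes x samples nonnegative ints
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    gwas_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts is not None and self.counts.shape[1] != len(self.metadata):
            raise ValueError("counts columns != metadata rows")
        if self.log_expression.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("log_expression shape inconsistent with ids")
        known = set(self.gene_ids)
        for name, members in self.marker_sets.items():
            if not set(members) <= known:
                raise ValueError(f"marker set {name!r} references unknown genes")
        if not set(self.gwas_set) <= known:
            raise ValueError("gwas_set references unknown genes")

    def expression_matrix(self):
        from .preprocess import ExpressionMatrix

        return ExpressionMatrix(
            self.log_expression, self.gene_ids, self.sample_ids, scale="log_cpm"
        )


def _arm(start_xy, angle, arm_length, n_new, coords, edges, attach):
    """Append a straight chain of *n_new* vertices leaving *attach*."""
    step = arm_length / n_new
    d = np.array([np.cos(angle), np.sin(angle)])
    prev = attach
    for s in range(1, n_new + 1):
        coords.append(np.asarray(start_xy) + s * step * d)
        idx = len(coords) - 1
        edges.append((prev, idx))
        prev = idx
    return prev  # tip index


def generate_tree_topology(
    topology_name: str,
    arm_length: float = 5.0,
    n_vertices_per_arm: int = 5,
    seed: int = 0,
) -> TrueTree:
    """Build a named latent topology: ``path`` (one segment), ``y`` (three
    arms off one hub) or ``double_y`` (two hubs, four outer arms).

    Each arm spans *arm_length* and carries *n_vertices_per_arm* vertices
    counting its hub endpoint.  The root is the tip of the first arm.
    """
    if n_vertices_per_arm < 2:
        raise ValueError("n_vertices_per_arm must be >= 2")
    if arm_length <= 0:
        raise ValueError("arm_length must be positive")
    n_new = n_vertices_per_arm - 1  # vertices added per arm beyond the hub
    coords: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    if topology_name == "path":
        coords.append(np.zeros(2))
        _arm((0.0, 0.0), 0.0, arm_length, n_new, coords, edges, 0)
        root = 0
    elif topology_name == "y":
        coords.append(np.zeros(2))  # hub
        root = _arm((0.0, 0.0), np.pi, arm_length, n_new, coords, edges, 0)
        _arm((0.0, 0.0), np.pi / 3, arm_length, n_new, coords, edges, 0)
        _arm((0.0, 0.0), -np.pi / 3, arm_length, n_new, coords, edges, 0)
    elif topology_name == "double_y":
        coords.append(np.zeros(2))  # hub A
        hub_b = _arm((0.0, 0.0), 0.0, arm_length, n_new, coords, edges, 0)
        xy_b = coords[hub_b]
        root = _arm((0.0, 0.0), 3 * np.pi / 4, arm_length, n_new, coords, edges, 0)
        _arm((0.0, 0.0), -3 * np.pi / 4, arm_length, n_new, coords, edges, 0)
        _arm(xy_b, np.pi / 4, arm_length, n_new, coords, edges, hub_b)
        _arm(xy_b, -np.pi / 4, arm_length, n_new, coords, edges, hub_b)
    else:
        raise ValueError(f"unknown topology_name: {topology_name!r}")
    return TrueTree(np.vstack(coords), edges, root, topology_name)


def sample_latent_positions(
    tree: TrueTree,
    n_samples: int,
    seed: int = 0,
    branch_weights: dict[int, float] | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Place samples on the tree uniformly by arc length (optionally
    reweighting branches) and record true pseudotime and branch.

    True pseudotime is the geodesic distance from the root, min-max scaled
    to [0, 1]; the branch label comes from the degree-!=2 decomposition.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    g = tree.graph()
    if g.number_of_edges() == 0:
        raise ValueError("degenerate tree with a single vertex")
    rng = named_rng(seed, "latent_positions")
    edge_list = [(min(i, j), max(i, j)) for i, j in tree.edges]
    lengths = np.array([g.edges[e]["length"] for e in edge_list])
    branch_of = branch_decomposition(g)
    weights = lengths.copy()
    if branch_weights is not None:
        for k, e in enumerate(edge_list):
            weights[k] *= float(branch_weights.get(branch_of[e], 1.0))
    probs = weights / weights.sum()
    edge_idx = rng.choice(len(edge_list), size=n_samples, p=probs)
    offset = rng.uniform(0.0, 1.0, size=n_samples)  # fraction along the edge
    dist = vertex_distances(g, tree.root_vertex)
    positions = np.empty((n_samples, 2))
    raw = np.empty(n_samples)
    branch = np.empty(n_samples, dtype=int)
    for s in range(n_samples):
        a, b = edge_list[edge_idx[s]]
        ln = lengths[edge_idx[s]]
        t = offset[s]
        positions[s] = tree.vertices[a] + t * (tree.vertices[b] - tree.vertices[a])
        raw[s] = min(dist[a] + t * ln, dist[b] + (1 - t) * ln)
        branch[s] = branch_of[(a, b)]
    if raw.max() == raw.min():
        raise ValueError("all samples coincide; cannot scale pseudotime")
    scaled = (raw - raw.min()) / (raw.max() - raw.min())
    truth = SyntheticTruth(tree=tree, true_pseudotime=scaled, true_branch=branch, seed=seed)
    return positions, truth


def _program_effects(
    truth: SyntheticTruth,
    programs: np.ndarray,
    params: dict[str, np.ndarray],
) -> np.ndarray:
    """Noise-free program effect matrix F (genes x samples): monotone
    logistic curves in pseudotime for increasing/decreasing genes,
    on-branch-only shifts for branch-specific genes, zero for flat."""
    t = truth.true_pseudotime
    n = t.size
    F = np.zeros((programs.size, n))
    amp, center, width, target_branch = (
        params["amplitude"],
        params["center"],
        params["width"],
        params["target_branch"],
    )
    for g, prog in enumerate(programs):
        if prog == "increasing":
            F[g] = amp[g] * expit((t - center[g]) / width[g])
        elif prog == "decreasing":
            F[g] = -amp[g] * expit((t - center[g]) / width[g])
        elif prog == "branch_specific":
            F[g] = np.where(truth.true_branch == target_branch[g], amp[g], 0.0)
    return F


def _negbin(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + mu^2/dispersion."""
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def generate_expression(
    positions: np.ndarray,
    truth: SyntheticTruth,
    n_genes: int = 2000,
    frac_increasing: float = 0.15,
    frac_decreasing: float = 0.15,
    frac_branch_specific: float = 0.10,
    noise_sd: float = 1.0,
    nb_dispersion: float = 10.0,
    mean_library_size: float = 1e6,
    mode: str = "linear_gaussian",
    seed: int = 0,
    latent_scale: float = 10.0,
    program_amplitude: float = 2.0,
) -> GeneratedCohort:
    """Generate expression from latent positions plus planted gene programs.

    ``linear_gaussian``: log-scale expression
    ``X = latent_scale * W_true @ positions.T + F + Gaussian(noise_sd)``
    with column-orthonormal ``W_true`` and F the program-effect matrix.
    Rows of ``W_true`` are nonzero only for program genes, so flat genes
    are exact nulls (pure noise); with ``program_amplitude=0`` (F = 0)
    the noiseless matrix is exactly rank 2 after gene-centering.

    ``negbin_counts``: per-gene rate ``exp(beta0_g + F_gi)`` scaled by a
    log-normal library size with mean *mean_library_size*, sampled
    negative-binomially with the given dispersion; ``log_expression`` is
    then log2(CPM + 1).

    Marker sets (neuron = decreasing; microglia / astrocyte /
    oligodendrocyte = increasing) and a 60-gene "GWAS" set (increasing)
    are designated among the program genes.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    fracs = (frac_increasing, frac_decreasing, frac_branch_specific)
    if any(f < 0 for f in fracs) or sum(fracs) > 1:
        raise ValueError("program fractions must be nonnegative and sum to <= 1")
    if mode not in ("linear_gaussian", "negbin_counts"):
        raise ValueError(f"unknown mode: {mode!r}")
    rng = named_rng(seed, "expression")
    n_samples = positions.shape[0]
    gene_ids = [f"G{g + 1:05d}" for g in range(n_genes)]
    sample_ids = [f"S{s + 1:04d}" for s in range(n_samples)]

    n_inc = int(round(frac_increasing * n_genes))
    n_dec = int(round(frac_decreasing * n_genes))
    n_bs = int(round(frac_branch_specific * n_genes))
    programs = np.array(
        ["increasing"] * n_inc
        + ["decreasing"] * n_dec
        + ["branch_specific"] * n_bs
        + ["flat"] * (n_genes - n_inc - n_dec - n_bs)
    )
    rng.shuffle(programs)

    branch_ids = sorted(set(truth.true_branch.tolist()))
    params = {
        "amplitude": program_amplitude * rng.uniform(0.5, 1.5, size=n_genes),
        "center": rng.uniform(0.25, 0.75, size=n_genes),
        "width": rng.uniform(0.08, 0.15, size=n_genes),
        "target_branch": rng.choice(branch_ids, size=n_genes),
    }
    F = _program_effects(truth, programs, params)

    if mode == "linear_gaussian":
        nonflat = np.flatnonzero(programs != "flat")
        W_true = np.zeros((n_genes, 2))
        if nonflat.size >= 2:
            W_true[nonflat], _ = np.linalg.qr(rng.standard_normal((nonflat.size, 2)))
        X = latent_scale * (W_true @ positions.T) + F
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
        counts = None
        log_expression = X
    else:
        beta0 = rng.normal(3.0, 1.0, size=n_genes)
        rate = np.exp(beta0[:, None] + F)
        rate = rate / rate.sum(axis=0, keepdims=True)
        lib = mean_library_size * np.exp(
            rng.normal(-0.3**2 / 2, 0.3, size=n_samples)
        )
        mu = rate * lib[None, :]
        counts = _negbin(rng, mu, nb_dispersion).astype(np.int64)
        libsize = counts.sum(axis=0).astype(float)
        libsize[libsize == 0] = 1.0
        log_expression = np.log2(counts / libsize * 1e6 + 1.0)

    truth.gene_programs = {
        gid: (
            prog
            if prog != "branch_specific"
            else f"branch_specific({int(params['target_branch'][g])})"
        )
        for g, (gid, prog) in enumerate(zip(gene_ids, programs))
    }

    inc_genes = [gid for gid, p in zip(gene_ids, programs) if p == "increasing"]
    dec_genes = [gid for gid, p in zip(gene_ids, programs) if p == "decreasing"]
    marker_sets: dict[str, list[str]] = {}
    m = max(1, min(40, len(inc_genes) // 4, len(dec_genes))) if inc_genes and dec_genes else 0
    if m:
        marker_sets = {
            "neuron": dec_genes[:m],
            "microglia": inc_genes[:m],
            "astrocyte": inc_genes[m : 2 * m],
            "oligodendrocyte": inc_genes[2 * m : 3 * m],
        }
    gwas_set = inc_genes[3 * m : 3 * m + 60] if inc_genes else []

    metadata = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    metadata["true_pseudotime"] = truth.true_pseudotime
    metadata["true_branch"] = truth.true_branch
    return GeneratedCohort(
        log_expression=log_expression,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        metadata=metadata,
        counts=counts,
        marker_sets=marker_sets,
        gwas_set=gwas_set,
    )


def generate_clinical_labels(
    truth: SyntheticTruth,
    logistic_a: float = -2.0,
    logistic_b: float = 4.0,
    ordinal_cutpoints: tuple[float, ...] = (-1.0, 0.5, 2.0),
    ordinal_b: float = 2.0,
    dosage_a: float = -1.5,
    dosage_b: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw diagnosis, an ordinal neuropathology-like score and an allele
    dosage, all stochastically monotone in true pseudotime.

    P(case) = expit(logistic_a + logistic_b * t); the ordinal score uses
    the proportional-odds convention P(Y <= j) = expit(theta_j -
    ordinal_b * t) with strictly increasing cutpoints theta; dosage ~
    Binomial(2, expit(dosage_a + dosage_b * t)).
    """
    cut = np.asarray(ordinal_cutpoints, dtype=float)
    if cut.size < 1 or np.any(np.diff(cut) <= 0):
        raise ValueError("ordinal_cutpoints must be strictly increasing")
    t = truth.true_pseudotime
    rng = named_rng(seed, "clinical_labels")
    case = rng.uniform(size=t.size) < expit(logistic_a + logistic_b * t)
    # P(Y <= j) for j = 1..J-1; level = 1 + #{j : U > P(Y <= j)} drawn by inversion
    cum = expit(cut[None, :] - ordinal_b * t[:, None])
    u = rng.uniform(size=t.size)
    score = 1 + (u[:, None] > cum).sum(axis=1)
    dosage = rng.binomial(2, expit(dosage_a + dosage_b * t))
    truth.label_params = {
        "logistic_a": logistic_a,
        "logistic_b": logistic_b,
        "ordinal_cutpoints": list(map(float, cut)),
        "ordinal_b": ordinal_b,
        "dosage_a": dosage_a,
        "dosage_b": dosage_b,
    }
    return pd.DataFrame(
        {
            "diagnosis": np.where(case, "case", "control"),
            "score": score,
            "dosage": dosage,
        }
    )


def plant_resistant_controls(
    cohort: GeneratedCohort,
    truth: SyntheticTruth,
    quantile_floor: float = 0.8,
    n_resistant: int = 9,
    cluster_size: int = 50,
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[GeneratedCohort, SyntheticTruth]:
    """Flag late-stage controls as "disease resistant" and upregulate a
    designated gene cluster in exactly those samples.

    Controls with true pseudotime above the *quantile_floor* empirical
    quantile (type-7, over all samples) are eligible; *n_resistant* of
    them are flagged and *cluster_size* flat genes get +*effect* added on
    the log scale in those samples only (counts, when present, are scaled
    by exp(effect) and floored).
    """
    if not 0 < quantile_floor < 1:
        raise ValueError("quantile_floor must be in (0, 1)")
    if "diagnosis" not in cohort.metadata.columns:
        raise ValueError("cohort metadata lacks a diagnosis column")
    rng = named_rng(seed, "resistant")
    t = truth.true_pseudotime
    thresh = np.quantile(t, quantile_floor)  # type-7 / linear interpolation
    is_control = (cohort.metadata["diagnosis"] == "control").to_numpy()
    eligible = np.flatnonzero(is_control & (t > thresh))
    if eligible.size < n_resistant:
        raise ValueError(
            f"only {eligible.size} control(s) above the {quantile_floor} "
            f"pseudotime quantile; {n_resistant} requested"
        )
    chosen = np.sort(rng.choice(eligible, size=n_resistant, replace=False))
    flat = [g for g, gid in enumerate(cohort.gene_ids) if truth.gene_programs[gid] == "flat"]
    if len(flat) < cluster_size:
        raise ValueError(f"only {len(flat)} flat genes available for a cluster of {cluster_size}")
    cluster = np.sort(rng.choice(flat, size=cluster_size, replace=False))

    new_cohort = copy.deepcopy(cohort)
    new_truth = copy.deepcopy(truth)
    new_cohort.log_expression[np.ix_(cluster, chosen)] += effect
    if new_cohort.counts is not None:
        block = new_cohort.counts[np.ix_(cluster, chosen)].astype(float)
        new_cohort.counts[np.ix_(cluster, chosen)] = np.floor(block * np.exp(effect)).astype(np.int64)
    resistant_genes = [cohort.gene_ids[g] for g in cluster]
    resistant_samples = [cohort.sample_ids[s] for s in chosen]
    for gid in resistant_genes:
        new_truth.gene_programs[gid] = "resistant_cluster"
    new_truth.resistant_genes = resistant_genes
    new_truth.resistant_samples = resistant_samples
    new_cohort.metadata = new_cohort.metadata.copy()
    new_cohort.metadata["resistant"] = [
        sid in set(resistant_samples) for sid in new_cohort.sample_ids
    ]
    return new_cohort, new_truth


def simulate_cohort(
    topology: str = "y",
    n_samples: int = 300,
    n_genes: int = 2000,
    seed: int = 0,
    mode: str = "linear_gaussian",
    plant_resistance: bool = True,
    n_resistant: int | str = "auto",
    resistant_effect: float = 2.0,
    **expression_kwargs,
) -> tuple[GeneratedCohort, SyntheticTruth]:
    """One-call cohort: topology, latent positions, expression, clinical
    labels, and (optionally) the planted resistant-control cluster, all
    driven by a single master seed."""
    tree = generate_tree_topology(topology, seed=seed)
    positions, truth = sample_latent_positions(tree, n_samples, seed=seed)
    cohort = generate_expression(
        positions, truth, n_genes=n_genes, mode=mode, seed=seed, **expression_kwargs
    )
    labels = generate_clinical_labels(truth, seed=seed)
    labels.index = cohort.metadata.index
    cohort.metadata = pd.concat([cohort.metadata, labels], axis=1)
    if plant_resistance:
        if n_resistant == "auto":
            # target 9 late-stage controls, falling back to however many the
            # label draw produced (late controls are rare under a slope-4
            # case model, so the count fluctuates across seeds)
            thresh = np.quantile(truth.true_pseudotime, 0.8)
            eligible = int(
                (
                    (cohort.metadata["diagnosis"] == "control")
                    & (truth.true_pseudotime > thresh)
                ).sum()
            )
            if eligible < 2:
                raise ValueError("too few late-stage controls to plant resistance")
            n_resistant = min(9, eligible)
        cohort, truth = plant_resistant_controls(
            cohort, truth, n_resistant=n_resistant, effect=resistant_effect, seed=seed
        )
    return cohort, truth
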