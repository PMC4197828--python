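"""Synthetic data with known ground truth for every stage of the pipeline.

The generators emulate the statistical structure the downstream analysis
assumes: dye-swapped two-colour hybridisations with an intensity-dependent
dye bias and a hierarchical gene-variance model, log-ratio profiles drawn
from a volume-varying Gaussian mixture with a shared orientation/shape
matrix, promoters with motifs planted in preferential windows relative to
the TSS, and annotation/edge tables with planted high-degree nodes.  Every
generator is a pure function of its parameters and a seed, and every
planted signal is recorded in a :class:`SimTruth` so that recovery can be
checked independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .motifs import IUPAC_CODES, PromoterSet

#: The seven contrasts of the reference design: wild type response to the
#: flagellin epitope, the three kinase mutants against wild type under
#: control conditions, and each mutant's flagellin response.
DEFAULT_COMPARISONS: tuple[str, ...] = (
    "col_flg22_vs_col",
    "mpk3_vs_col",
    "mpk4_vs_col",
    "mpk6_vs_col",
    "mpk3_flg22_vs_mpk3",
    "mpk4_flg22_vs_mpk4",
    "mpk6_flg22_vs_mpk6",
)


@dataclass(frozen=True)
class ArrayDesign:
    """Layout of a dye-swapped two-colour hybridisation experiment.

    Each biological replicate of each contrast is hybridised twice, once
    with the fluorochromes reversed, and each gene is represented by
    ``duplicate_probes`` probes (one per strand on the reference array).
    """

    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    replicates_per_comparison: int = 3
    dye_swap: bool = True
    duplicate_probes: int = 2

    def __post_init__(self) -> None:
        if len(self.comparisons) == 0:
            raise ValueError("comparisons must be non-empty")
        if self.replicates_per_comparison < 1:
            raise ValueError("replicates_per_comparison must be >= 1")
        if self.duplicate_probes < 1:
            raise ValueError("duplicate_probes must be >= 1")

    @property
    def n_hybridisations(self) -> int:
        per_rep = 2 if self.dye_swap else 1
        return len(self.comparisons) * self.replicates_per_comparison * per_rep


@dataclass
class SimTruth:
    """Ground truth recorded by the generators.

    Fields are filled by whichever generator produced the object; unused
    components stay ``None``.
    """

    true_logratio: pd.DataFrame | None = None  # genes x comparisons
    de_flags: pd.DataFrame | None = None  # genes x comparisons, bool
    cluster_labels: pd.Series | None = None  # gene -> component (-1 = none)
    motif_windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_occurrences: pd.DataFrame | None = None  # motif, gene, position
    hub_genes: set[str] = field(default_factory=set)
    variance_params: dict | None = None  # d0, s0_sq and per-gene sigma_sq

    def validate(self) -> None:
        if self.true_logratio is not None and self.de_flags is not None:
            expected = self.true_logratio.abs().gt(0)
            if not expected.equals(self.de_flags):
                raise ValueError("de_flags inconsistent with true_logratio")
        if self.variance_params is not None:
            sigma = np.asarray(self.variance_params["sigma_sq"])
            if not np.all(sigma > 0):
                raise ValueError("gene variances must be positive")


def gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


def _draw_gene_variances(rng, n_genes: int, d0: float, s0_sq: float) -> np.ndarray:
    """sigma_g^2 ~ scaled inverse chi-square(d0, s0^2), the moderated-t prior."""
    if np.isinf(d0):
        return np.full(n_genes, s0_sq)
    return d0 * s0_sq / rng.chisquare(d0, size=n_genes)


def gen_two_colour_arrays(
    design: ArrayDesign,
    n_genes: int,
    de_fraction: float = 0.1,
    effect_size: float = 2.0,
    bias_curve: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
    *,
    d0: float = 4.0,
    s0_sq: float = 0.05,
    tech_sd: float = 0.05,
    intensity_range: tuple[float, float] = (6.0, 16.0),
    patterns: np.ndarray | None = None,
    min_intensity: float = 1e-6,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate probe-level red/green intensities for a full design.

    The measured log-ratio of a spot is
    ``M = o * (true effect + biological deviation) + bias_curve(A) + technical noise``
    where ``o`` is -1 on dye-reversed hybridisations, the biological
    deviation is shared by the dye pair of a replicate and has gene
    variance sigma_g^2 drawn from a scaled inverse chi-square (d0, s0^2)
    prior, and A (the mean log2 intensity) is uniform on
    ``intensity_range``.  Channels are reconstructed as R = 2^(A + M/2),
    G = 2^(A - M/2) and floored at ``min_intensity``.

    If ``patterns`` (a (n_patterns, n_comparisons) array of prototype
    profiles) is given, differentially expressed genes take a whole
    prototype row as their true profile and the pattern index is recorded
    as a cluster label; otherwise each gene x comparison cell is non-zero
    independently with probability ``de_fraction`` and effect
    ``+/- effect_size``.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    comparisons = list(design.comparisons)
    n_comp = len(comparisons)
    n_rep = design.replicates_per_comparison
    swaps = [False, True] if design.dye_swap else [False]
    n_probe = design.duplicate_probes

    truth_lr = np.zeros((n_genes, n_comp))
    labels = np.full(n_genes, -1)
    if patterns is not None:
        patterns = np.asarray(patterns, dtype=float)
        if patterns.shape[1] != n_comp:
            raise ValueError("patterns must have one column per comparison")
        is_de = rng.random(n_genes) < de_fraction
        idx = rng.integers(0, patterns.shape[0], size=n_genes)
        truth_lr[is_de] = patterns[idx[is_de]]
        labels[is_de] = idx[is_de]
    else:
        de_cells = rng.random((n_genes, n_comp)) < de_fraction
        signs = rng.choice([-1.0, 1.0], size=(n_genes, n_comp))
        truth_lr[de_cells] = (signs * effect_size)[de_cells]

    sigma_sq = _draw_gene_variances(rng, n_genes, d0, s0_sq)

    # Biological deviation per (gene, comparison, replicate), shared by the
    # dye pair so that averaging over technical replicates leaves exactly
    # one independent value per biological replicate.
    bio = rng.normal(size=(n_genes, n_comp, n_rep)) * np.sqrt(sigma_sq)[:, None, None]

    frames = []
    for ci, comp in enumerate(comparisons):
        for rep in range(1, n_rep + 1):
            m_bio = truth_lr[:, ci] + bio[:, ci, rep - 1]
            for swap in swaps:
                orient = -1.0 if swap else 1.0
                a = rng.uniform(*intensity_range, size=(n_genes, n_probe))
                noise = rng.normal(scale=tech_sd, size=(n_genes, n_probe)) if tech_sd > 0 else 0.0
                m_raw = orient * m_bio[:, None] + noise
                if bias_curve is not None:
                    m_raw = m_raw + bias_curve(a)
                red = np.maximum(2.0 ** (a + m_raw / 2.0), min_intensity)
                green = np.maximum(2.0 ** (a - m_raw / 2.0), min_intensity)
                for p in range(n_probe):
                    frames.append(
                        pd.DataFrame(
                            {
                                "probe_id": [f"{g}_p{p + 1}" for g in genes],
                                "gene_id": genes,
                                "comparison": comp,
                                "bio_rep": rep,
                                "dye_swap": swap,
                                "R": red[:, p],
                                "G": green[:, p],
                            }
                        )
                    )
    table = pd.concat(frames, ignore_index=True)

    truth = SimTruth(
        true_logratio=pd.DataFrame(truth_lr, index=genes, columns=comparisons),
        de_flags=pd.DataFrame(truth_lr != 0.0, index=genes, columns=comparisons),
        cluster_labels=pd.Series(labels, index=genes, name="cluster"),
        variance_params={"d0": d0, "s0_sq": s0_sq, "sigma_sq": pd.Series(sigma_sq, index=genes)},
    )
    truth.validate()
    return table, truth


def gen_mixture_profiles(
    n: int,
    d: int,
    K: int,
    proportions: Sequence[float],
    means: np.ndarray,
    volumes: Sequence[float],
    shape_matrix: np.ndarray,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw rows from sum_k pi_k N(mu_k, lambda_k * C) with det(C) = 1.

    Returns the profile matrix (rows ``obs00001``..., columns
    ``dim1``...) and the planted component labels.
    """
    proportions = np.asarray(proportions, dtype=float)
    means = np.asarray(means, dtype=float).reshape(K, d)
    volumes = np.asarray(volumes, dtype=float)
    C = np.asarray(shape_matrix, dtype=float)
    if not np.isclose(proportions.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    if np.any(volumes <= 0):
        raise ValueError("volumes must be positive")
    if C.shape != (d, d) or not np.allclose(C, C.T):
        raise ValueError("shape_matrix must be symmetric d x d")
    if abs(np.linalg.det(C) - 1.0) > 1e-8:
        raise ValueError("shape_matrix must have unit determinant")
    np.linalg.cholesky(C)  # raises if not positive definite

    rng = np.random.default_rng(seed)
    labels = rng.choice(K, size=n, p=proportions)
    chol = np.linalg.cholesky(C)
    z = rng.normal(size=(n, d))
    X = means[labels] + np.sqrt(volumes[labels])[:, None] * (z @ chol.T)
    frame = pd.DataFrame(
        X,
        index=[f"obs{i:05d}" for i in range(n)],
        columns=[f"dim{j + 1}" for j in range(d)],
    )
    return frame, labels


def unit_det_shape(matrix: np.ndarray) -> np.ndarray:
    """Rescale a symmetric positive-definite matrix to unit determinant."""
    matrix = np.asarray(matrix, dtype=float)
    d = matrix.shape[0]
    det = np.linalg.det(matrix)
    if det <= 0:
        raise ValueError("matrix must be positive definite")
    return matrix / det ** (1.0 / d)


def _validate_iupac(motif: str) -> str:
    motif = motif.upper()
    bad = set(motif) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC letters in motif {motif!r}: {sorted(bad)}")
    return motif


def _realise_motif(rng, motif: str) -> str:
    return "".join(rng.choice(list(IUPAC_CODES[ch])) for ch in motif)


def gen_promoters(
    n_genes: int,
    length: int = 1000,
    planted: Sequence[tuple[str, Iterable[str], tuple[int, int], float]] = (),
    gc: float = 0.36,
    seed: int = 0,
) -> tuple[PromoterSet, SimTruth]:
    """Simulate fixed-length TSS-anchored promoters with planted motifs.

    The background is i.i.d. with the given GC content.  Each ``planted``
    entry is ``(iupac, target genes, (a, b) window, planting probability)``
    with the window in TSS-relative coordinates (closed interval inside
    ``[-length, -1]``); a planted occurrence is a concrete realisation of
    the IUPAC pattern placed uniformly so the whole match lies inside the
    window.  Planting positions (the match base closest to the TSS) are
    recorded in the returned truth.
    """
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    base_probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = rng.choice(list("ACGT"), size=(n_genes, length), p=base_probs)

    windows: dict[str, tuple[int, int]] = {}
    records = []
    gene_index = {g: i for i, g in enumerate(genes)}
    for motif, targets, (a, b), prob in planted:
        motif = _validate_iupac(motif)
        m = len(motif)
        if not (-length <= a <= b <= -1):
            raise ValueError(f"window ({a}, {b}) outside promoter [-{length}, -1]")
        if m > b - a + 1:
            raise ValueError("motif longer than its window")
        windows[motif] = (a, b)
        for g in targets:
            if rng.random() >= prob:
                continue
            start = int(rng.integers(a, b - m + 2))  # leftmost base, inclusive
            realised = _realise_motif(rng, motif)
            idx = length + start
            seqs[gene_index[g], idx : idx + m] = list(realised)
            records.append({"motif": motif, "gene_id": g, "position": start + m - 1})

    promoters = PromoterSet({g: "".join(row) for g, row in zip(genes, seqs)})
    truth = SimTruth(
        motif_windows=windows,
        planted_occurrences=pd.DataFrame(records, columns=["motif", "gene_id", "position"]),
    )
    return promoters, truth


def _default_term_size(rng) -> int:
    return int(np.ceil(rng.lognormal(mean=2.5, sigma=0.8)))


def gen_annotations_and_edges(
    n_genes: int,
    n_terms: int = 20,
    term_size_law: Callable | None = None,
    ppi_density: float = 0.002,
    tf_target_count: int = 100,
    planted_hubs: Sequence[tuple[str, int]] = (),
    seed: int = 0,
    hub_partner_pool: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a GO annotation table and PPI / TF-target edge lists.

    Planted hubs are guaranteed at least their requested degree (distinct
    neighbours); edge lists contain no self-loops and no duplicates.
    ``hub_partner_pool`` restricts the genes a planted hub connects to
    (e.g. to keep a hub's neighbourhood inside a gene set of interest);
    by default partners are drawn from all genes.
    """
    max_edges = n_genes * (n_genes - 1) // 2
    if ppi_density < 0 or round(ppi_density * max_edges) > max_edges:
        raise ValueError("requested density implies more edges than pairs")
    for g, deg in planted_hubs:
        if deg >= n_genes:
            raise ValueError(f"planted degree {deg} for {g} needs >= {deg + 1} genes")
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    term_size = term_size_law or _default_term_size

    go_rows = []
    for t in range(n_terms):
        size = int(np.clip(term_size(rng), 1, n_genes))
        for g in rng.choice(n_genes, size=size, replace=False):
            go_rows.append({"gene_id": genes[g], "term_id": f"GO:{t:07d}"})
    go = pd.DataFrame(go_rows, columns=["gene_id", "term_id"]).drop_duplicates()

    n_ppi = rng.binomial(max_edges, ppi_density) if ppi_density > 0 else 0
    ppi_pairs: set[tuple[int, int]] = set()
    while len(ppi_pairs) < n_ppi:
        a, b = rng.integers(0, n_genes, size=2)
        if a != b:
            ppi_pairs.add((min(a, b), max(a, b)))

    neighbours: dict[int, set[int]] = {}
    for a, b in ppi_pairs:
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)
    gene_index = {g: i for i, g in enumerate(genes)}
    pool = (
        [gene_index[g] for g in hub_partner_pool]
        if hub_partner_pool is not None
        else list(range(n_genes))
    )
    for g, deg in planted_hubs:
        gi = gene_index[g] if isinstance(g, str) else int(g)
        if deg >= len(pool):
            raise ValueError(f"planted degree {deg} exceeds the partner pool size")
        have = neighbours.setdefault(gi, set())
        while len(have) < deg:
            other = int(pool[rng.integers(0, len(pool))])
            if other == gi or other in have:
                continue
            have.add(other)
            neighbours.setdefault(other, set()).add(gi)
            ppi_pairs.add((min(gi, other), max(gi, other)))

    tf_pairs: set[tuple[int, int]] = set()
    while len(tf_pairs) < tf_target_count:
        a, b = rng.integers(0, n_genes, size=2)
        if a != b:
            tf_pairs.add((int(a), int(b)))

    ppi = pd.DataFrame(
        [{"a": genes[a], "b": genes[b], "type": "ppi"} for a, b in sorted(ppi_pairs)],
        columns=["a", "b", "type"],
    )
    tf = pd.DataFrame(
        [{"a": genes[a], "b": genes[b], "type": "tf_target"} for a, b in sorted(tf_pairs)],
        columns=["a", "b", "type"],
    )
    return go, ppi, tf
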