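"""Hypergeometric term enrichment and kinetic class assignment.

Cluster enrichment compares the relative occurrence of an annotation term
inside a cluster to its relative occurrence in the annotated genome by a
one-sided hypergeometric test; the same machinery serves for GO terms and
for kinetic response classes.  Kinetic classes summarise a gene's fold
change at 1 h and 3 h after elicitation into ten trajectories: F-J for
induction (transient, decreasing, sustained, increasing, late) and A-E
mirroring them for repression, with a two-fold rule discriminating the
decreasing / sustained / increasing shapes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_pvalues

UP_CLASSES = ("F", "G", "H", "I", "J")
DOWN_CLASSES = ("A", "B", "C", "D", "E")
ALL_CLASSES = DOWN_CLASSES + UP_CLASSES


def hypergeom_enrichment(
    cluster_genes: Iterable[str],
    annotation: pd.DataFrame,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of annotation terms in a cluster.

    ``annotation`` has columns gene_id, term_id.  The background is the
    annotated part of the universe (N genes, K_term per term); for a
    cluster with n annotated genes of which k carry the term, the
    p-value is the exact upper tail P(X >= k) of
    Hypergeometric(N, K_term, n).  Every term with k >= 1 is reported,
    with the occurrence ratio (k/n) / (K_term/N), the raw p-value, a
    Benjamini-Hochberg column, and the significance call at ``alpha``
    (on the raw p-value, matching a raw-threshold convention).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    cluster = set(cluster_genes)
    if not cluster <= universe:
        raise ValueError("cluster genes must be contained in the universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    annotated = set(ann["gene_id"])
    N = len(annotated)
    if N == 0:
        raise ValueError("no annotated genes in the universe")
    cluster_ann = cluster & annotated
    n = len(cluster_ann)
    rows = []
    for term, sub in ann.groupby("term_id", sort=True):
        term_genes = set(sub["gene_id"])
        K_term = len(term_genes)
        k = len(cluster_ann & term_genes)
        if k < 1:
            continue
        ratio = (k / n) / (K_term / N) if n else np.nan
        p = float(stats.hypergeom.sf(k - 1, N, K_term, n))
        rows.append({"term_id": term, "k": k, "n": n, "K_term": K_term, "N": N,
                     "ratio": ratio, "pvalue": p})
    result = pd.DataFrame(rows, columns=["term_id", "k", "n", "K_term", "N", "ratio", "pvalue"])
    if len(result):
        result["p_bh"] = adjust_pvalues(result["pvalue"].to_numpy(), "bh")
        result["significant"] = result["pvalue"] < alpha
    else:
        result["p_bh"] = []
        result["significant"] = []
    return result


def classify_kinetics(fc_1h: float, fc_3h: float, induced_threshold: float = 2.0) -> str:
    """Assign one gene to a kinetic class from its 1 h / 3 h fold changes.

    Fold changes are on the linear scale.  ``induced`` means
    fc >= induced_threshold, ``repressed`` means fc <= 1/induced_threshold,
    anything between is basal.  Induction branch: F induced then back to
    basal; G induced at both times, at least two-fold weaker at 3 h;
    H induced at both times within two-fold; I at least two-fold stronger
    at 3 h; J basal at 1 h, induced at 3 h.  A-E mirror F-J for
    repression (on reciprocal fold changes).  Trajectories that switch
    sign (induced then repressed, or the reverse) and genes basal at both
    times are ``unclassified``.
    """
    if fc_1h <= 0 or fc_3h <= 0:
        raise ValueError("fold changes must be positive")
    T = float(induced_threshold)
    i1, i3 = fc_1h >= T, fc_3h >= T
    r1, r3 = fc_1h <= 1.0 / T, fc_3h <= 1.0 / T
    if i1 and i3:
        if fc_1h / fc_3h >= 2.0:
            return "G"
        if fc_3h / fc_1h >= 2.0:
            return "I"
        return "H"
    if i1 and not i3 and not r3:
        return "F"
    if i3 and not i1 and not r1:
        return "J"
    if r1 and r3:
        rep1, rep3 = 1.0 / fc_1h, 1.0 / fc_3h
        if rep1 / rep3 >= 2.0:
            return "B"
        if rep3 / rep1 >= 2.0:
            return "D"
        return "C"
    if r1 and not r3 and not i3:
        return "A"
    if r3 and not r1 and not i1:
        return "E"
    return "unclassified"


def classify_kinetics_table(
    reference: pd.DataFrame, induced_threshold: float = 2.0
) -> pd.Series:
    """Vector version over a (gene_id, fc_1h, fc_3h) reference table."""
    labels = [
        classify_kinetics(row.fc_1h, row.fc_3h, induced_threshold)
        for row in reference.itertuples()
    ]
    return pd.Series(labels, index=reference["gene_id"].to_numpy(), name="kinetic_class")


def class_enrichment(
    cluster_genes: Iterable[str],
    classes: Mapping[str, str] | pd.Series,
    universe: Iterable[str] | None = None,
    which: Sequence[str] = ALL_CLASSES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of kinetic classes inside a cluster.

    Treats each class label as an annotation term; classes with no genes
    get p = 1.  ``universe`` defaults to every gene in the class table.
    """
    classes = pd.Series(classes)
    universe = set(universe) if universe is not None else set(classes.index)
    cluster = set(cluster_genes) & universe
    N = len(universe)
    n = len(cluster)
    if N == 0 or n == 0:
        raise ValueError("empty universe or cluster")
    rows = []
    for cls in which:
        members = set(classes.index[classes == cls]) & universe
        K_cls = len(members)
        k = len(cluster & members)
        p = float(stats.hypergeom.sf(k - 1, N, K_cls, n))
        rows.append({"class": cls, "k": k, "n": n, "K_class": K_cls, "N": N,
                     "pvalue": p, "significant": p < alpha})
    return pd.DataFrame(rows)
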