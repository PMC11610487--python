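"""GO over-representation, p-value-profile clustering of terms, and the
cross-species rhythmic-overlap test.

Annotations are used exactly as supplied (no propagation up the GO graph);
the default population for over-representation is the analyzed gene set.
Term p-value profiles across condition columns are compared with a summed
absolute-difference distance and clustered agglomeratively so functionally
concordant terms sit together regardless of which condition drove them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import ValidationError
from .rhythm_tests import bh_adjust

__all__ = ["read_annotation", "read_ortholog_map", "go_overrep",
           "pvalue_term_clustering", "cross_species_overlap"]

MIN_TERM_SIZE = 2  # terms with < 2 population genes are noise-prone; skipped


def read_annotation(path) -> pd.DataFrame:
    """Two-column TSV gene_id -> GO accession ('GO:NNNNNNN'), one pair per row."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"],
                     dtype=str, comment="#")
    bad = ~df["term"].str.fullmatch(r"GO:\d{7}")
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} malformed GO accessions")
    return df


def read_ortholog_map(path) -> pd.DataFrame:
    """Two-column TSV source_gene_id -> target_gene_id (many-to-many)."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["source", "target"], dtype=str, comment="#")


def go_overrep(study, population, annot: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of GO terms.

    study and population are gene-id collections (study must be a subset of
    the population); annot maps gene_id -> term. Terms without study hits or
    with fewer than MIN_TERM_SIZE population genes are skipped. Returns a
    table with counts, upper-tail p = P(X >= hits), and BH q over the tested
    terms.
    """
    study = set(map(str, study))
    population = set(map(str, population))
    if not study <= population:
        raise ValidationError("study set must be a subset of the population")
    ann = annot[annot["gene_id"].astype(str).isin(population)]
    term_genes = ann.groupby("term")["gene_id"].agg(lambda s: set(map(str, s)))
    N = len(population)
    n_study = len(study)
    rows = []
    for term, genes in term_genes.items():
        K = len(genes)
        if K < MIN_TERM_SIZE:
            continue
        k = len(genes & study)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n_study))
        rows.append({"term": term, "hits": k, "study_size": n_study,
                     "term_size": K, "population_size": N,
                     "p": min(1.0, max(p, np.finfo(float).tiny))})
    out = pd.DataFrame(rows, columns=["term", "hits", "study_size", "term_size",
                                      "population_size", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.array([])
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def pvalue_term_clustering(p_table: pd.DataFrame, linkage_method: str = "complete",
                           ) -> tuple[np.ndarray, list]:
    """Hierarchical clustering of terms by their p-value profiles.

    p_table: terms (index) × condition columns of p-values, untested cells
    filled with 1. Distance between two terms is the sum over columns of
    |p_a - p_b| (a city-block metric on the profile). Returns the scipy
    linkage matrix and the leaf-order term list for plotting.
    """
    if len(p_table) < 2:
        return np.empty((0, 4)), list(p_table.index)
    X = p_table.to_numpy(dtype=float)
    d = pdist(X, metric="cityblock")
    Z = hierarchy.linkage(d, method=linkage_method)
    order = hierarchy.leaves_list(Z)
    return Z, [p_table.index[i] for i in order]


def cross_species_overlap(foreign_rhythmic, ortholog_map: pd.DataFrame,
                          native_rhythmic, universe) -> dict:
    """Is the ortholog-mapped foreign rhythmic set enriched for native
    rhythmic genes?

    The foreign gene list is mapped through the (possibly many-to-many)
    ortholog table, deduplicated, and restricted to the universe; the overlap
    with the native rhythmic set is scored with an upper-tail hypergeometric
    test (population = universe, successes = native rhythmic, draws = mapped
    set)."""
    universe = set(map(str, universe))
    native = set(map(str, native_rhythmic)) & universe
    foreign = set(map(str, foreign_rhythmic))
    mapped = set(
        ortholog_map.loc[ortholog_map["source"].astype(str).isin(foreign), "target"]
        .astype(str)
    ) & universe
    if not mapped:
        return {"mapped": 0, "overlap": 0, "p": float("nan"), "defined": False}
    overlap = len(mapped & native)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(native), len(mapped)))
    return {"mapped": len(mapped), "overlap": overlap,
            "p": min(1.0, p), "defined": True}
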