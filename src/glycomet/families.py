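"""Family-level comparative analysis across environments.

Rows of the I_ms family-by-environment matrix are clustered hierarchically
(Euclidean distance, Ward linkage), families are labelled general / moderate /
specific by how many environments they are prevalent in, substrate-class
enrichment between groups is tested with 2x2 chi-squared tests, and the EC
numbers of general families are mapped onto a pathway EC list to compute
coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import chi2_contingency

from .refdb import SubstrateTable

logger = logging.getLogger(__name__)

GROUP_LABELS = ("general", "moderate", "specific")

#: Substrate classes counted as "complex carbohydrate" in enrichment tests.
POLY_OLIGO = ("polysaccharide", "oligosaccharide")


@dataclass
class ClusterResult:
    labels: list[str]          # row labels in input order
    linkage_matrix: np.ndarray  # scipy linkage format
    leaf_order: list[str]      # labels in dendrogram order
    metric: str = "euclidean"
    method: str = "ward"

    def to_newick(self) -> str:
        """Newick string with branch lengths from the merge heights."""
        n = len(self.labels)
        if n == 1:
            return f"{self.labels[0]};"

        def height(node: int) -> float:
            return 0.0 if node < n else float(self.linkage_matrix[node - n, 2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.labels[node]}:{bl:.6g}"
            row = self.linkage_matrix[node - n]
            a, b = self._ordered_children(int(row[0]), int(row[1]))
            h = height(node)
            return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

        root = 2 * n - 2
        row = self.linkage_matrix[-1]
        a, b = self._ordered_children(int(row[0]), int(row[1]))
        h = height(root)
        return f"({render(a, h)},{render(b, h)});"

    def _min_leaf(self, node: int) -> int:
        n = len(self.labels)
        if node < n:
            return node
        row = self.linkage_matrix[node - n]
        return min(self._min_leaf(int(row[0])), self._min_leaf(int(row[1])))

    def _ordered_children(self, a: int, b: int) -> tuple[int, int]:
        return (a, b) if self._min_leaf(a) <= self._min_leaf(b) else (b, a)


def cluster_ims(matrix: pd.DataFrame) -> ClusterResult:
    """Ward/Euclidean hierarchical clustering of the family rows.

    Leaf order is made deterministic by always placing the child subtree that
    contains the smallest original row index first. A single-row matrix
    yields a trivial single-leaf tree with a warning.
    """
    if matrix.isna().any().any():
        raise ValueError("I_ms matrix contains missing cells")
    labels = [str(i) for i in matrix.index]
    if len(labels) < 2:
        logger.warning("clustering a single-row matrix is trivial")
        return ClusterResult(labels, np.empty((0, 4)), list(labels))
    Z = linkage(matrix.to_numpy(dtype=float), method="ward",
                metric="euclidean")
    result = ClusterResult(labels, Z, [])

    def leaves(node: int) -> list[int]:
        if node < len(labels):
            return [node]
        row = Z[node - len(labels)]
        a, b = result._ordered_children(int(row[0]), int(row[1]))
        return leaves(a) + leaves(b)

    result.leaf_order = [labels[i] for i in leaves(2 * len(labels) - 2)]
    return result


def group_families(matrix: pd.DataFrame, tau: float = 0.5,
                   general_min: int = 11,
                   specific_max: int = 3) -> dict[str, str]:
    """Label every family general / moderate / specific.

    A family is *present* in an environment when I_ms >= tau. Families
    present in at least ``general_min`` environments are general, in at most
    ``specific_max`` are specific, and moderate otherwise. The defaults suit
    a twelve-environment survey; pass bounds matching the number of matrix
    columns for smaller designs.
    """
    n_env = matrix.shape[1]
    if not (0 <= specific_max < general_min <= n_env):
        raise ValueError(
            f"need specific_max < general_min <= n_environments "
            f"({specific_max=}, {general_min=}, {n_env=})")
    present = (matrix >= tau).sum(axis=1)
    out = {}
    for fam, n in present.items():
        if n >= general_min:
            out[str(fam)] = "general"
        elif n <= specific_max:
            out[str(fam)] = "specific"
        else:
            out[str(fam)] = "moderate"
    return out


def substrate_enrichment(groups: dict[str, str],
                         substrates: SubstrateTable) -> dict:
    """Fraction of polysaccharide/oligosaccharide families per group, with
    pairwise 2x2 chi-squared tests (no continuity correction).

    Returns ``{"fractions": DataFrame, "tests": DataFrame}``; groups with no
    families get a NaN fraction and their pairwise tests are skipped.
    """
    counts = {g: [0, 0] for g in GROUP_LABELS}  # [poly+oligo, other]
    for fam, group in groups.items():
        cls = substrates.lookup(fam)
        counts[group][0 if cls in POLY_OLIGO else 1] += 1
    frac_rows = []
    for g in GROUP_LABELS:
        po, other = counts[g]
        total = po + other
        frac_rows.append((g, po, other,
                          po / total if total else np.nan))
    fractions = pd.DataFrame(
        frac_rows, columns=["group", "poly_oligo", "other", "fraction"])
    test_rows = []
    for i, a in enumerate(GROUP_LABELS):
        for b in GROUP_LABELS[i + 1:]:
            table = np.array([counts[a], counts[b]])
            if table.sum(axis=1).min() == 0:
                logger.warning("group with 0 families; skipping %s vs %s",
                               a, b)
                continue
            if table.sum(axis=0).min() == 0:
                stat, p = 0.0, 1.0  # degenerate margin: no association
            else:
                stat, p, _, _ = chi2_contingency(table, correction=False)
            test_rows.append((a, b, float(stat), float(p)))
    tests = pd.DataFrame(test_rows,
                         columns=["group_a", "group_b", "chi2", "p_value"])
    return {"fractions": fractions, "tests": tests}


def pathway_coverage(general_ecs: Sequence[str],
                     pathway_ecs: Sequence[str],
                     pathway_name: str = "pathway") -> dict:
    """Coverage of a pathway's EC set by the general-family EC numbers."""
    pathway = {e.strip() for e in pathway_ecs if str(e).strip()}
    if not pathway:
        raise ValueError("empty pathway EC list")
    mapped = pathway & {e.strip() for e in general_ecs}
    return {"pathway": pathway_name, "pathway_size": len(pathway),
            "mapped": len(mapped), "coverage": len(mapped) / len(pathway),
            "mapped_ecs": sorted(mapped)}


def load_ec_list(path: str | Path) -> list[str]:
    """One EC number per line (blank lines and # comments ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def load_family_ec_table(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV family -> semicolon-separated EC numbers."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {str(r.iloc[0]): str(r.iloc[1]).split(";")
            for _, r in df.iterrows()}
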