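"""Core domain objects and I/O for OTU-table ecology.

The central objects are :class:`CommunityTable` (an integer OTU x sample
count matrix with per-sample group labels and optional environmental
variables), :class:`PhyloTree` (a rooted phylogeny over the OTU tips) and
:class:`DistanceMatrix` (cophenetic distances between tips).  Everything
downstream -- rarefaction, abundance classification, phylogenetic null
models and co-occurrence networks -- consumes these types.

Conventions
-----------
* matrices are OTUs-as-rows, samples-as-columns;
* relative abundances are fractions (0.01% == 1e-4), never percentages;
* random operations take an explicit integer seed; there is no global
  random state.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "PhyloTree",
    "RelAbundance",
    "DistanceMatrix",
    "read_community_table",
    "write_community_table",
    "read_newick",
    "write_newick",
    "rarefy_counts",
    "relative_abundance",
    "cophenetic_matrix",
    "match_tree_to_table",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (dimensions, labels, signs)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Integer OTU x sample count matrix plus sample metadata.

    Parameters
    ----------
    otu_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integer read counts.
    sample_groups : dict
        Maps every sample id to a group label (e.g. ``"monsoon"``).
    env : pandas.DataFrame, optional
        Samples x environmental-variables table (temperature, nutrients,
        chlorophyll a, ...), indexed by sample id.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_groups: dict[str, str]
    env: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.sample_groups]
        if missing:
            raise ValidationError(f"samples missing a group label: {missing}")
        if self.env is not None and not set(self.sample_ids) <= set(self.env.index):
            raise ValidationError("env table does not cover all samples")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.sample_groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def group_vector(self) -> np.ndarray:
        return np.array([self.sample_groups[s] for s in self.sample_ids])

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def subset_otus(self, otu_ids: list[str]) -> "CommunityTable":
        """Restrict to the given OTUs (counts untouched, order preserved)."""
        index = {o: k for k, o in enumerate(self.otu_ids)}
        unknown = [o for o in otu_ids if o not in index]
        if unknown:
            raise ValidationError(f"unknown OTU ids: {unknown[:5]}")
        rows = [index[o] for o in otu_ids]
        return CommunityTable(
            otu_ids=list(otu_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts[rows, :],
            sample_groups=dict(self.sample_groups),
            env=self.env,
        )

    def subset_samples(self, sample_ids: list[str]) -> "CommunityTable":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return CommunityTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, cols],
            sample_groups={s: self.sample_groups[s] for s in sample_ids},
            env=self.env.loc[sample_ids] if self.env is not None else None,
        )


@dataclass
class RelAbundance:
    """Per-sample relative abundances on the same axes as a CommunityTable."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_groups: dict[str, str]
    env: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match id lists")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError("relative abundances must lie in [0, 1]")
        totals = self.values.sum(axis=0)
        bad = ~(np.isclose(totals, 1.0, atol=1e-9) | np.isclose(totals, 0.0))
        if np.any(bad):
            raise ValidationError(
                f"sample columns must sum to 1 (or 0): {np.asarray(self.sample_ids)[bad]}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class PhyloTree:
    """Rooted, branch-length-bearing phylogeny over OTU tips.

    Thin wrapper around a :class:`dendropy.Tree` that enforces unique tip
    labels and non-negative branch lengths.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        n_missing = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                n_missing += 1
            elif edge.length < 0:
                raise ValidationError("negative branch length")
        if n_missing:
            logger.warning("%d edges without branch lengths set to 0", n_missing)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValidationError("diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValidationError("negative distances")

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        index = {l: k for k, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise ValidationError(f"labels not in matrix: {missing[:5]}")
        idx = np.array([index[l] for l in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_community_table(path, metadata_path) -> CommunityTable:
    """Read a counts TSV plus a sample-metadata TSV.

    Counts: header row of sample ids, first column ``#OTU ID``.  Metadata:
    columns ``sample_id``, ``group``, then free environmental columns.
    Metadata rows for unknown samples are ignored with a warning; table
    samples without metadata are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-integer count {raw!r} at OTU {df.index[i]!r}, sample {col!r}"
                ) from None
            if v < 0:
                raise ValidationError(
                    f"negative count at OTU {df.index[i]!r}, sample {col!r}"
                )
            counts[i, j] = v

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValidationError("metadata must have 'sample_id' and 'group' columns")
    meta = meta.set_index("sample_id")
    unknown = [s for s in meta.index if s not in set(df.columns)]
    if unknown:
        logger.warning("metadata for unknown samples ignored: %s", unknown)
        meta = meta.drop(index=unknown)
    missing = [s for s in df.columns if s not in set(meta.index)]
    if missing:
        raise ValidationError(f"samples without metadata/group label: {missing}")

    env_cols = [c for c in meta.columns if c != "group"]
    env = meta[env_cols].astype(float) if env_cols else None
    return CommunityTable(
        otu_ids=list(df.index),
        sample_ids=list(df.columns),
        counts=counts,
        sample_groups=meta["group"].to_dict(),
        env=env,
    )


def write_community_table(table: CommunityTable, path, metadata_path) -> None:
    """Write counts + metadata in the same dialect :func:`read_community_table` reads."""
    df = table.to_dataframe()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")
    meta = pd.DataFrame({"group": [table.sample_groups[s] for s in table.sample_ids]},
                        index=pd.Index(table.sample_ids, name="sample_id"))
    if table.env is not None:
        meta = meta.join(table.env.loc[table.sample_ids])
    meta.to_csv(metadata_path, sep="\t")


def read_newick(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    if hasattr(path, "read"):
        src = path.read()
    else:
        with open(path) as fh:
            src = fh.read()
    try:
        tree = dendropy.Tree.get(data=src, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"could not parse Newick: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path) -> None:
    text = tree.as_newick() + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_newick_string(newick: str) -> PhyloTree:
    """Parse a Newick string (convenience for fixtures and tests)."""
    return read_newick(io.StringIO(newick))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def rarefy_counts(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Equivalent to drawing ``depth`` reads from the sample's read pool
    (multivariate hypergeometric), the standard normalisation that puts all
    samples on an equal sequencing depth before diversity and null-model
    analyses.  Samples with fewer than ``depth`` reads are an error; nothing
    is silently dropped.
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    totals = table.sample_totals()
    small = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if small:
        raise ValidationError(
            f"samples with fewer than {depth} reads: {small}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(len(table.sample_ids)):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return CommunityTable(
        otu_ids=list(table.otu_ids),
        sample_ids=list(table.sample_ids),
        counts=out,
        sample_groups=dict(table.sample_groups),
        env=table.env,
    )


def relative_abundance(table: CommunityTable) -> RelAbundance:
    """Per-sample fractions; an all-zero sample stays all-zero (warned)."""
    totals = table.sample_totals().astype(float)
    zero = totals == 0
    if np.any(zero):
        logger.warning(
            "all-zero samples left as zero columns: %s",
            [s for s, z in zip(table.sample_ids, zero) if z],
        )
    safe = np.where(zero, 1.0, totals)
    values = table.counts / safe
    return RelAbundance(
        otu_ids=list(table.otu_ids),
        sample_ids=list(table.sample_ids),
        values=values,
        sample_groups=dict(table.sample_groups),
        env=table.env,
    )


def cophenetic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Patristic (sum of branch lengths on the path) distances between tips.

    Computed by a single post-order pass: at every internal node the
    distance between tips in different child subtrees is the sum of their
    distances to that node, filled blockwise.
    """
    leaves = list(tree.tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): k for k, leaf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    # node -> (tip indices below it, distance of each tip to the node)
    below: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = (np.array([index[id(node)]]), np.zeros(1))
            continue
        groups = []
        for child in node.child_nodes():
            idx, dist = below.pop(id(child))
            groups.append((idx, dist + (child.edge.length or 0.0)))
        for a in range(len(groups)):
            ia, da = groups[a]
            for b in range(a + 1, len(groups)):
                ib, db = groups[b]
                block = da[:, None] + db[None, :]
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        below[id(node)] = (
            np.concatenate([g[0] for g in groups]),
            np.concatenate([g[1] for g in groups]),
        )
    return DistanceMatrix(labels, D)


def match_tree_to_table(tree: PhyloTree, table: CommunityTable) -> PhyloTree:
    """Prune tree tips absent from the table; table OTUs missing from the
    tree are a hard error (nearest-taxon null models are undefined for them).
    """
    tips = set(tree.tip_labels)
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        raise ValidationError(
            f"{len(missing)} table OTUs missing from the tree, e.g. {missing[:5]}"
        )
    extra = tips - set(table.otu_ids)
    if extra:
        logger.warning("pruning %d tree tips absent from the table", len(extra))
        pruned = tree.tree.clone(depth=1)
        keep = [t for t in pruned.taxon_namespace if t.label in set(table.otu_ids)]
        pruned.retain_taxa(keep)
        return PhyloTree(pruned)
    return tree
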