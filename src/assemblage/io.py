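"""Read, validate and harmonize community tables, taxonomies, metadata and trees.

A dataset is a samples x ASVs integer count matrix with per-sample metadata
(treatment group, day, replicate), per-ASV taxonomy strings, and a rooted
phylogeny whose tips are the ASVs.  Every downstream null model consumes the
:class:`Dataset` produced by :func:`harmonize`.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("assemblage")

__all__ = [
    "ValidationError",
    "CommunityTable",
    "Phylogeny",
    "Dataset",
    "read_community_table",
    "read_tree",
    "parse_newick",
    "harmonize",
    "write_dataset",
    "read_dataset",
    "genus_of",
]

REQUIRED_METADATA = ("group", "day", "replicate")


class ValidationError(ValueError):
    """A file parsed but its content violates a dataset invariant."""


def genus_of(taxonomy: str) -> str:
    """Genus from a semicolon-ranked taxonomy string.

    The 6th rank is taken as genus when present and non-empty; otherwise the
    last non-empty rank; otherwise ``"unclassified"``.
    """
    ranks = [r.strip() for r in str(taxonomy).split(";")]
    if len(ranks) >= 6 and ranks[5]:
        return ranks[5]
    for r in reversed(ranks):
        if r:
            return r
    return "unclassified"


@dataclass
class CommunityTable:
    """Samples x ASVs count matrix with sample metadata and ASV taxonomy.

    ``counts`` is an integer DataFrame indexed by sample id with ASV-id
    columns. ``metadata`` is indexed by sample id with columns
    ``group``/``day``/``replicate``; ``taxonomy`` maps ASV id -> ranked string.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValidationError(f"duplicate sample ids: {sorted(c.index[c.index.duplicated()])}")
        if c.columns.duplicated().any():
            raise ValidationError(f"duplicate ASV ids: {sorted(c.columns[c.columns.duplicated()])}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float storage only if integral-valued
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(arr != np.floor(arr))
                r, k = bad[0]
                raise ValidationError(
                    f"non-integer count at sample {c.index[r]!r}, ASV {c.columns[k]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            r, k = np.argwhere(arr < 0)[0]
            raise ValidationError(f"negative count at sample {c.index[r]!r}, ASV {c.columns[k]!r}")
        missing = set(c.index) - set(self.metadata.index)
        if missing:
            raise ValidationError(f"metadata missing samples: {sorted(missing)}")
        if self.metadata.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        self.metadata = self.metadata.loc[c.index]
        # taxonomy: fill absent ASVs as unclassified rather than erroring
        self.taxonomy = self.taxonomy.reindex(c.columns).fillna("unclassified")
        # drop zero-total samples with a warning (partially failed replicates)
        totals = arr.sum(axis=1)
        if (totals == 0).any():
            dropped = list(c.index[totals == 0])
            logger.warning("dropping zero-total samples: %s", dropped)
            self.counts = c = c.loc[totals > 0]
            self.metadata = self.metadata.loc[c.index]
        if len(self.counts) == 0:
            raise ValidationError("no samples with positive total counts")

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def genera(self) -> pd.Series:
        """Genus label per ASV (see :func:`genus_of`)."""
        return self.taxonomy.map(genus_of)

    def subset_samples(self, sample_ids) -> "CommunityTable":
        ids = list(sample_ids)
        return CommunityTable(self.counts.loc[ids].copy(), self.metadata.loc[ids].copy(), self.taxonomy.copy())

    def subset_asvs(self, asv_ids) -> "CommunityTable":
        ids = [a for a in self.asv_ids if a in set(asv_ids)]
        return CommunityTable(self.counts[ids].copy(), self.metadata.copy(), self.taxonomy.loc[ids].copy())

    def groups(self) -> list[str]:
        return list(pd.unique(self.metadata["group"]))

    def group_table(self, group: str) -> "CommunityTable":
        ids = self.metadata.index[self.metadata["group"] == group]
        if len(ids) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return self.subset_samples(ids)


class Phylogeny:
    """Rooted phylogeny with branch lengths, backed by a scikit-bio tree.

    Validation requires a single root, unique tip labels and a branch length
    on every non-root edge (a missing length is an error, never silently 0).
    Internal arrays (parent pointers, edge lengths, per-edge descendant tip
    masks) are precomputed for the phylogenetic metrics.
    """

    def __init__(self, tree: skbio.TreeNode):
        tree = tree.copy()
        tips = list(tree.tips())
        names = [t.name for t in tips]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate tip labels: {dup}")
        if any(n is None for n in names):
            raise ValidationError("unnamed tip in tree")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                desc = ",".join(sorted(t.name for t in node.tips())) or node.name or "?"
                raise ValidationError(f"missing branch length on edge above [{desc}]")
            if node.length < 0:
                raise ValidationError("negative branch length")
        if tree.length is None:
            tree.length = 0.0
        self._tree = tree
        self._build_arrays()

    def _build_arrays(self) -> None:
        nodes = list(self._tree.postorder(include_self=True))
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self._parent = np.full(n, -1, dtype=np.int64)
        self._length = np.zeros(n)
        self._is_tip = np.zeros(n, dtype=bool)
        for i, node in enumerate(nodes):
            if node.parent is not None:
                self._parent[i] = index[id(node.parent)]
            self._length[i] = node.length or 0.0
            self._is_tip[i] = node.is_tip()
        self._tip_nodes = np.flatnonzero(self._is_tip)
        self._tip_names = [nodes[i].name for i in self._tip_nodes]
        self._tip_index = {name: i for name, i in zip(self._tip_names, self._tip_nodes)}
        # per-edge descendant tip mask: mask[node, tip_position]
        ntips = len(self._tip_nodes)
        tip_pos = {node_i: p for p, node_i in enumerate(self._tip_nodes)}
        mask = np.zeros((n, ntips), dtype=bool)
        for i in range(n):  # postorder: children precede parents
            if self._is_tip[i]:
                mask[i, tip_pos[i]] = True
            p = self._parent[i]
            if p >= 0:
                mask[p] |= mask[i]
        self._tip_mask = mask
        self._patristic_cache: tuple[list[str], np.ndarray] | None = None

    # -- basic properties ----------------------------------------------------
    @property
    def tree(self) -> skbio.TreeNode:
        return self._tree

    @property
    def tip_names(self) -> list[str]:
        return list(self._tip_names)

    @property
    def n_tips(self) -> int:
        return len(self._tip_names)

    @property
    def total_branch_length(self) -> float:
        return float(self._length.sum())

    def tip_path_edges(self, name: str) -> np.ndarray:
        """Indices of edges on the root-to-tip path of ``name`` (tip first)."""
        try:
            i = self._tip_index[name]
        except KeyError:
            raise KeyError(f"unknown tip {name!r}") from None
        path = []
        while i >= 0 and self._parent[i] >= 0:
            path.append(i)
            i = self._parent[i]
        return np.asarray(path, dtype=np.int64)

    def patristic(self) -> tuple[list[str], np.ndarray]:
        """Tip labels and the dense tip-to-tip (patristic) distance matrix."""
        if self._patristic_cache is None:
            dm = self._tree.tip_tip_distances()
            ids = list(dm.ids)
            self._patristic_cache = (ids, np.asarray(dm.data, dtype=float))
        ids, mat = self._patristic_cache
        return ids, mat.copy()

    def shear(self, names) -> "Phylogeny":
        """Subtree induced by ``names`` (lengths of collapsed paths summed)."""
        keep = set(names)
        missing = keep - set(self._tip_names)
        if missing:
            raise KeyError(f"unknown tips: {sorted(missing)}")
        return Phylogeny(self._tree.shear(keep))

    def write(self, path) -> None:
        self._tree.write(str(path), format="newick")

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass
class Dataset:
    """A community table and a phylogeny sharing exactly the same ASV set."""

    table: CommunityTable
    tree: Phylogeny

    def __post_init__(self) -> None:
        if set(self.table.asv_ids) != set(self.tree.tip_names):
            raise ValidationError("table ASV set != tree tip set; call harmonize() first")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def read_community_table(counts_path, taxonomy_path, metadata_path,
                         orientation: str = "auto") -> CommunityTable:
    """Read the three tab-separated inputs into a validated table.

    The counts file may hold samples as rows or as columns; with
    ``orientation='auto'`` the header's index-column name decides
    (``sample_id`` -> rows are samples, ``asv_id`` -> rows are ASVs), falling
    back to matching row labels against the metadata sample ids.
    """
    counts = _read_tsv(counts_path, index_col=0)
    meta = _read_tsv(metadata_path, index_col=0)
    tax_df = _read_tsv(taxonomy_path, index_col=0)
    if tax_df.shape[1] < 1:
        raise ValidationError(f"{taxonomy_path}: expected an id column and a taxonomy column")
    taxonomy = tax_df.iloc[:, 0].astype(str)

    label = (counts.index.name or "").strip().lstrip("#").lower()
    if orientation == "auto":
        if label in {"sample", "sample_id", "sampleid"}:
            orientation = "samples"
        elif label in {"asv", "asv_id", "otu", "otu_id", "feature_id"}:
            orientation = "asvs"
        elif set(counts.index) <= set(meta.index):
            orientation = "samples"
        elif set(counts.columns) <= set(meta.index):
            orientation = "asvs"
        else:
            raise ValidationError(
                f"{counts_path}: cannot auto-detect orientation; "
                "name the index column 'sample_id' or 'asv_id'"
            )
    if orientation == "asvs":
        counts = counts.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")

    num = counts.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        r, k = np.argwhere(num.isna().to_numpy())[0]
        raise ValidationError(
            f"{counts_path}: malformed numeric cell at sample {num.index[r]!r}, ASV {num.columns[k]!r}"
        )
    return CommunityTable(num, meta, taxonomy)


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick string into a validated :class:`Phylogeny`."""
    try:
        tree = skbio.TreeNode.read(_io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValidationError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def read_tree(newick_path) -> Phylogeny:
    """Read one rooted Newick tree; polytomies allowed, lengths required."""
    text = Path(newick_path).read_text().strip()
    if not text:
        raise ValidationError(f"{newick_path}: empty file")
    return parse_newick(text)


def harmonize(table: CommunityTable, tree: Phylogeny) -> Dataset:
    """Restrict table and tree to their shared ASVs (>= 2 required).

    ASVs absent from the tree are dropped from the table with a logged
    warning; the tree is pruned to the table's ASVs. Idempotent.
    """
    shared = [a for a in table.asv_ids if a in set(tree.tip_names)]
    if len(shared) < 2:
        raise ValidationError(
            f"only {len(shared)} ASV(s) shared between table and tree; need >= 2"
        )
    dropped = set(table.asv_ids) - set(shared)
    if dropped:
        logger.warning("dropping %d ASVs absent from tree", len(dropped))
        table = table.subset_asvs(shared)
    if set(tree.tip_names) != set(shared):
        tree = tree.shear(shared)
    return Dataset(table, tree)


def _header_comment(params: dict | None) -> str:
    from . import __version__

    items = {"assemblage_version": __version__, **(params or {})}
    return "".join(f"# {k}={v}\n" for k, v in items.items())


def write_dataset(dataset_or_table, outdir, params: dict | None = None) -> dict[str, Path]:
    """Write counts/taxonomy/metadata TSVs (and the tree, for a Dataset).

    Every table carries a ``#`` header comment recording the package version
    plus any run parameters (seed, randomization counts, ...).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(dataset_or_table, Dataset):
        table, tree = dataset_or_table.table, dataset_or_table.tree
    else:
        table, tree = dataset_or_table, None
    head = _header_comment(params)
    paths = {}

    def _write(name: str, df: pd.DataFrame, index_label: str) -> None:
        p = outdir / name
        with open(p, "w") as fh:
            fh.write(head)
            df.to_csv(fh, sep="\t", index_label=index_label)
        paths[name.split(".")[0]] = p

    _write("counts.tsv", table.counts, "sample_id")
    _write("metadata.tsv", table.metadata, "sample_id")
    _write("taxonomy.tsv", table.taxonomy.to_frame("taxonomy"), "asv_id")
    if tree is not None:
        p = outdir / "tree.nwk"
        tree.write(p)
        paths["tree"] = p
    return paths


def read_dataset(indir) -> Dataset:
    """Read a directory written by :func:`write_dataset` back into a Dataset."""
    indir = Path(indir)
    table = read_community_table(indir / "counts.tsv", indir / "taxonomy.tsv", indir / "metadata.tsv")
    tree = read_tree(indir / "tree.nwk")
    return harmonize(table, tree)
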