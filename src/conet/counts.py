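"""Taxon count tables: reading, filtering, taxonomic grouping, and transforms.

A count table holds non-negative read counts of taxonomic features (OTUs,
ESVs, or lineage-collapsed taxa) across samples, optionally annotated with
seven-rank taxonomy lineages.  The operations here mirror the standard
"OTU processing" stage of an amplicon workflow: drop shallow samples and
sparse features, collapse counts to a taxonomic rank, and normalize
(total-sum scaling, centered log-ratio, or rarefaction).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "Lineage",
    "CountTable",
    "EmptyTableError",
    "filter_counts",
    "group_taxa",
    "transform",
    "read_tsv",
    "write_tsv",
    "read_taxonomy_tsv",
    "read_biom",
    "write_biom",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

# QIIME/Greengenes style rank prefixes such as "g__" in "g__Prevotella"
_PREFIX_RE = re.compile(r"^[a-zA-Z]__")


class EmptyTableError(ValueError):
    """Raised when a filtering step removes every sample or feature."""


@dataclass(frozen=True)
class Lineage:
    """A seven-rank taxonomy lineage (kingdom .. species).

    Unresolved ranks are empty strings and may only occur as a suffix: a
    feature resolved to family level has empty genus and species slots.
    The string form is the semicolon-joined prefix of non-empty ranks.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError(f"lineage must have exactly 7 ranks, got {len(self.ranks)}")
        seen_empty = False
        for r in self.ranks:
            if r == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"empty ranks must form a suffix, got {self.ranks!r}"
                )

    @classmethod
    def from_string(cls, s: str) -> "Lineage":
        parts = [p.strip() for p in s.split(";")] if s.strip() else []
        parts = [_PREFIX_RE.sub("", p) for p in parts]
        # drop trailing empties left by prefixes like "g__;s__"
        while parts and parts[-1] == "":
            parts.pop()
        if len(parts) > 7:
            raise ValueError(f"lineage {s!r} has more than 7 ranks")
        parts += [""] * (7 - len(parts))
        return cls(tuple(parts))

    @property
    def depth(self) -> int:
        """Number of resolved (non-empty) ranks."""
        return sum(1 for r in self.ranks if r != "")

    def prefix(self, level: str) -> "Lineage":
        """Truncate to ``level`` (ranks below it emptied).

        If the lineage is unresolved at ``level`` the result is the deepest
        non-empty prefix, i.e. the lineage itself.
        """
        if level not in RANKS:
            raise ValueError(f"unknown rank {level!r}; expected one of {RANKS}")
        k = RANKS.index(level) + 1
        kept = tuple(self.ranks[:k]) + ("",) * (7 - k)
        return Lineage(kept)

    def __str__(self) -> str:
        return ";".join(r for r in self.ranks if r != "")


class CountTable:
    """Features x samples matrix of taxon counts with optional lineages.

    Parameters
    ----------
    counts
        2-D array-like, features in rows, samples in columns.
    feature_ids, sample_ids
        Unique string labels matching the matrix dimensions.
    lineages
        Optional per-feature :class:`Lineage`.
    normalization_state
        One of ``raw``, ``tss``, ``clr``, ``rarefied``.  Only the ``clr``
        state may contain negative entries.
    """

    STATES = ("raw", "tss", "clr", "rarefied")

    def __init__(
        self,
        counts,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
        lineages: Optional[Sequence[Lineage]] = None,
        normalization_state: str = "raw",
    ) -> None:
        mat = np.asarray(counts, dtype=float)
        if mat.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        feature_ids = [str(f) for f in feature_ids]
        sample_ids = [str(s) for s in sample_ids]
        if mat.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"counts shape {mat.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if len(set(feature_ids)) != len(feature_ids):
            raise ValueError("feature ids must be unique")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample ids must be unique")
        if normalization_state not in self.STATES:
            raise ValueError(f"unknown normalization state {normalization_state!r}")
        if normalization_state != "clr" and (mat < 0).any():
            raise ValueError("negative entries only allowed in clr state")
        if lineages is not None:
            lineages = list(lineages)
            if len(lineages) != len(feature_ids):
                raise ValueError("one lineage per feature required")
        self.data = pd.DataFrame(mat, index=feature_ids, columns=sample_ids)
        self.lineages: Optional[list[Lineage]] = lineages
        self.normalization_state = normalization_state

    # -- convenience accessors -------------------------------------------------
    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "CountTable":
        return CountTable(
            self.counts.copy(),
            self.feature_ids,
            self.sample_ids,
            None if self.lineages is None else list(self.lineages),
            self.normalization_state,
        )

    def _subset(self, rows: np.ndarray, cols: np.ndarray) -> "CountTable":
        lineages = None
        if self.lineages is not None:
            lineages = [self.lineages[i] for i in np.flatnonzero(rows)]
        return CountTable(
            self.counts[np.ix_(rows, cols)],
            [f for f, k in zip(self.feature_ids, rows) if k],
            [s for s, k in zip(self.sample_ids, cols) if k],
            lineages,
            self.normalization_state,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountTable({self.n_features} features x {self.n_samples} samples, "
            f"state={self.normalization_state!r})"
        )


def filter_counts(
    table: CountTable,
    prevalence_min: float = 0.05,
    abundance_min: float = 0.01,
    obs_sum_min: float = 100,
    sample_sum_min: float = 500,
) -> CountTable:
    """Remove shallow samples, then sparse / low-abundance features.

    Samples whose total reads fall below ``sample_sum_min`` are dropped
    first.  A feature is then removed if, over the retained samples, any of
    the following holds:

    * prevalence (fraction of samples with a nonzero count) < ``prevalence_min``
    * mean relative abundance < ``abundance_min``
    * total count < ``obs_sum_min``

    Defaults are the stringent "filter on" thresholds (prevalence 0.05,
    abundance 0.01, observation sum 100, sample sum 500); the relaxed
    "filter off" setting uses prevalence ``2/n_samples``, abundance 0.001
    and observation sum 10.
    """
    if table.normalization_state != "raw":
        raise ValueError("filtering requires raw counts")
    for name, val in (
        ("prevalence_min", prevalence_min),
        ("abundance_min", abundance_min),
        ("obs_sum_min", obs_sum_min),
        ("sample_sum_min", sample_sum_min),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    if not 0 <= prevalence_min <= 1:
        raise ValueError("prevalence_min must be in [0, 1]")
    if not 0 <= abundance_min <= 1:
        raise ValueError("abundance_min must be in [0, 1]")

    mat = table.counts
    sample_totals = mat.sum(axis=0)
    keep_samples = sample_totals >= sample_sum_min
    if not keep_samples.any():
        raise EmptyTableError(
            f"empty table after filtering: sample_sum_min={sample_sum_min} "
            "removed every sample"
        )
    sub = mat[:, keep_samples]
    totals = sub.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(totals > 0, sub / totals, 0.0)
    prevalence = (sub > 0).mean(axis=1)
    mean_abund = rel.mean(axis=1)
    obs_sum = sub.sum(axis=1)
    keep_features = (
        (prevalence >= prevalence_min)
        & (mean_abund >= abundance_min)
        & (obs_sum >= obs_sum_min)
    )
    if not keep_features.any():
        # name the threshold responsible for removing the most features
        kills = {
            f"prevalence_min={prevalence_min}": int((prevalence < prevalence_min).sum()),
            f"abundance_min={abundance_min}": int((mean_abund < abundance_min).sum()),
            f"obs_sum_min={obs_sum_min}": int((obs_sum < obs_sum_min).sum()),
        }
        worst = max(kills, key=kills.get)
        raise EmptyTableError(
            f"empty table after filtering: every feature removed ({worst} "
            f"alone fails {kills[worst]} of {table.n_features} features)"
        )
    return table._subset(keep_features, keep_samples)


def group_taxa(table: CountTable, level: str) -> CountTable:
    """Collapse features to a taxonomic rank by summing counts.

    Features sharing the identical lineage prefix up to ``level`` are
    summed into a single row keyed by that prefix string.  Features not
    resolved at ``level`` keep their deepest non-empty prefix as the key,
    so a family-only entity stays distinct from genus-resolved entities of
    the same family.  Column (per-sample) sums are conserved exactly.
    """
    if table.lineages is None:
        raise ValueError("group_taxa requires lineages")
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}; expected one of {RANKS}")

    keys: list[str] = []
    key_lineage: dict[str, Lineage] = {}
    for lin in table.lineages:
        pref = lin.prefix(level)
        key = str(pref)
        keys.append(key)
        key_lineage.setdefault(key, pref)

    order: list[str] = []
    seen = set()
    for k in keys:
        if k not in seen:
            seen.add(k)
            order.append(k)
    idx = {k: i for i, k in enumerate(order)}
    out = np.zeros((len(order), table.n_samples))
    for row, k in enumerate(keys):
        out[idx[k]] += table.counts[row]
    return CountTable(
        out,
        order,
        table.sample_ids,
        [key_lineage[k] for k in order],
        table.normalization_state,
    )


def transform(
    table: CountTable,
    method: str,
    depth: Optional[int] = None,
    pseudocount: Optional[float] = None,
    seed: Optional[int] = None,
) -> CountTable:
    """Normalize a raw count table.

    ``tss``
        Total-sum scaling; each sample (column) sums to 1.
    ``clr``
        Centered log-ratio: per sample, log((x + pseudocount) /
        geometric-mean(x + pseudocount)).  ``pseudocount`` defaults to 1
        and is required (> 0) whenever zeros are present.  Columns sum to
        0 up to numeric tolerance.
    ``rarefy``
        Subsample each sample without replacement to ``depth`` reads;
        reproducible under ``seed``.
    """
    if table.normalization_state != "raw":
        raise ValueError("transform requires raw counts")
    mat = table.counts

    if method == "tss":
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
            raise ValueError(f"tss undefined for all-zero samples: {bad}")
        out = mat / totals
        state = "tss"
    elif method == "clr":
        if pseudocount is None:
            pseudocount = 1.0
        if (mat == 0).any() and pseudocount <= 0:
            raise ValueError(
                "clr on zero-containing data requires a positive pseudocount"
            )
        shifted = mat + pseudocount
        if (shifted <= 0).any():
            raise ValueError("clr requires strictly positive shifted counts")
        logs = np.log(shifted)
        out = logs - logs.mean(axis=0)
        state = "clr"
    elif method == "rarefy":
        if depth is None:
            raise ValueError("rarefy requires a depth")
        depth = int(depth)
        totals = mat.sum(axis=0)
        shallow = [
            s for s, t in zip(table.sample_ids, totals) if t < depth
        ]
        if shallow:
            raise ValueError(
                f"rarefaction depth {depth} exceeds the total of sample(s) {shallow}"
            )
        rng = np.random.default_rng(seed)
        ints = np.rint(mat).astype(np.int64)
        if not np.allclose(ints, mat):
            raise ValueError("rarefaction requires integer counts")
        out = np.empty_like(mat)
        for j in range(table.n_samples):
            out[:, j] = rng.multivariate_hypergeometric(ints[:, j], depth)
        state = "rarefied"
    else:
        raise ValueError(f"unknown transform {method!r}; expected tss, clr or rarefy")

    return CountTable(
        out,
        table.feature_ids,
        table.sample_ids,
        None if table.lineages is None else list(table.lineages),
        state,
    )


# -- I/O ----------------------------------------------------------------------

def read_tsv(path, taxonomy_path=None) -> CountTable:
    """Read a features x samples TSV (first column feature id, header row
    sample ids), optionally joining a taxonomy TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lineages = None
    if taxonomy_path is not None:
        tax = read_taxonomy_tsv(taxonomy_path)
        missing = [f for f in df.index if str(f) not in tax]
        if missing:
            raise ValueError(f"taxonomy file lacks lineages for features {missing[:5]}")
        lineages = [tax[str(f)] for f in df.index]
    return CountTable(df.to_numpy(), df.index, df.columns, lineages)


def write_tsv(table: CountTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="#feature_id")


def read_taxonomy_tsv(path) -> dict[str, Lineage]:
    """Read a two-column TSV mapping feature id to a semicolon lineage."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    col = df.columns[0]
    return {str(i): Lineage.from_string(str(v)) for i, v in df[col].items()}


def read_biom(path) -> CountTable:
    """Read a BIOM table (HDF5 or JSON dialect) into a :class:`CountTable`.

    Lineages are taken from a per-observation ``taxonomy`` metadata entry
    when present.
    """
    import biom

    bt = biom.load_table(str(path))
    mat = np.asarray(bt.matrix_data.todense())
    feature_ids = list(bt.ids("observation"))
    sample_ids = list(bt.ids("sample"))
    lineages = None
    md = bt.metadata(axis="observation")
    if md is not None and all(m and "taxonomy" in m for m in md):
        lineages = []
        for m in md:
            tax = m["taxonomy"]
            if isinstance(tax, (list, tuple)):
                tax = ";".join(tax)
            lineages.append(Lineage.from_string(str(tax)))
    return CountTable(mat, feature_ids, sample_ids, lineages)


def write_biom(table: CountTable, path, fmt: str = "hdf5") -> None:
    """Write a :class:`CountTable` to BIOM (``fmt`` = ``hdf5`` or ``json``)."""
    import biom

    obs_md = None
    if table.lineages is not None:
        obs_md = [{"taxonomy": [r for r in lin.ranks if r]} for lin in table.lineages]
    bt = biom.Table(
        table.counts,
        observation_ids=table.feature_ids,
        sample_ids=table.sample_ids,
        observation_metadata=obs_md,
    )
    if fmt == "hdf5":
        import h5py

        with h5py.File(str(path), "w") as fh:
            bt.to_hdf5(fh, generated_by="conet")
    elif fmt == "json":
        with open(path, "w") as fh:
            fh.write(bt.to_json(generated_by="conet"))
    else:
        raise ValueError(f"unknown BIOM dialect {fmt!r}")
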