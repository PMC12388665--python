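"""Count tables, taxonomy and sample metadata: containers, readers/writers,
rarefaction and rank aggregation.

The count table is the universal currency of every downstream stage: an
integer taxa x samples matrix with unique row and column labels.  TSV is the
canonical on-disk format (taxa as rows, first column the taxon id, header row
the sample ids); BIOM is accepted read-only as a convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    ParameterError,
    TableFormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")

SITES = ("BYH", "ZYW", "LYH", "RYSD", "SW", "YQ", "JFD")
LAYERS = ("0-20 cm", "20-40 cm")

#: physicochemical variables carried by sample metadata (units in docs)
ENV_VARIABLES = ("pH", "WC", "TC", "TSC", "MBC", "TN", "AN", "TP", "AP", "TK", "AK")


class CountTable:
    """Integer taxa x samples abundance matrix with labelled axes.

    Parameters
    ----------
    counts : array-like of shape (n_taxa, n_samples)
        Non-negative integers.
    taxon_ids, sample_ids : sequences of unique strings
        Row and column labels.
    """

    def __init__(self, counts, taxon_ids, sample_ids):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        taxon_ids = [str(t) for t in taxon_ids]
        sample_ids = [str(s) for s in sample_ids]
        if len(taxon_ids) != counts.shape[0] or len(sample_ids) != counts.shape[1]:
            raise ValidationError("label counts do not match matrix dimensions")
        if len(set(taxon_ids)) != len(taxon_ids):
            raise ValidationError("duplicate taxon ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids")
        self._counts = counts.astype(np.int64, copy=True)
        self._counts.setflags(write=False)
        self._taxon_ids = tuple(taxon_ids)
        self._sample_ids = tuple(sample_ids)

    @property
    def counts(self) -> np.ndarray:
        return self._counts

    @property
    def taxon_ids(self) -> tuple:
        return self._taxon_ids

    @property
    def sample_ids(self) -> tuple:
        return self._sample_ids

    @property
    def shape(self) -> tuple:
        return self._counts.shape

    @property
    def n_taxa(self) -> int:
        return self._counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self._counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self._counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._counts.copy(),
            index=pd.Index(self._taxon_ids, name="taxon_id"),
            columns=list(self._sample_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self._sample_ids.index(s) for s in sample_ids]
        return CountTable(self._counts[:, idx], self._taxon_ids, sample_ids)

    def __eq__(self, other):
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self._taxon_ids == other._taxon_ids
            and self._sample_ids == other._sample_ids
            and np.array_equal(self._counts, other._counts)
        )

    def __repr__(self):
        return f"CountTable(n_taxa={self.n_taxa}, n_samples={self.n_samples})"


@dataclass(frozen=True)
class TaxonomyMap:
    """taxon_id -> ranked lineage (domain..genus); missing ranks are None."""

    lineages: dict = field(default_factory=dict)

    def rank_label(self, taxon_id: str, rank: str):
        if rank not in RANKS:
            raise ParameterError(f"unknown rank {rank!r}; expected one of {RANKS}")
        lineage = self.lineages.get(taxon_id)
        if lineage is None:
            return None
        return lineage[RANKS.index(rank)]


def parse_lineage(lineage: str) -> tuple:
    """Parse a semicolon-separated lineage string into the six fixed ranks.

    Both the prefixed convention ("d__Archaea;p__Crenarchaeota;...") and bare
    positional lineages ("Archaea;Crenarchaeota;...") are accepted; empty or
    missing fields become None.
    """
    parts = [p.strip() for p in lineage.split(";")]
    out = [None] * len(RANKS)
    prefixed = any(p[:3] in _RANK_PREFIXES for p in parts if len(p) >= 3)
    if prefixed:
        for p in parts:
            if len(p) >= 3 and p[:3] in _RANK_PREFIXES:
                i = _RANK_PREFIXES.index(p[:3])
                out[i] = p[3:] or None
    else:
        for i, p in enumerate(parts[: len(RANKS)]):
            out[i] = p or None
    return tuple(out)


class SampleMetadata:
    """Per-sample design factors (site, layer, replicate) plus physicochemical
    variables.

    The frame is indexed by sample_id.  Range invariants: WC in [0, 100],
    pH in (0, 14), all concentrations >= 0.
    """

    REQUIRED = ("site", "layer", "replicate")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if frame.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        if "pH" in frame.columns:
            ph = frame["pH"].to_numpy(dtype=float)
            if np.any((ph <= 0) | (ph >= 14)):
                raise ValidationError("pH out of (0, 14)")
        if "WC" in frame.columns:
            wc = frame["WC"].to_numpy(dtype=float)
            if np.any((wc < 0) | (wc > 100)):
                raise ValidationError("WC out of [0, 100]")
        for var in ENV_VARIABLES:
            if var in ("pH", "WC") or var not in frame.columns:
                continue
            if np.any(frame[var].to_numpy(dtype=float) < 0):
                raise ValidationError(f"negative concentration in {var}")
        self.frame = frame.copy()
        self.frame.index.name = "sample_id"

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.frame.index)

    def env_frame(self, variables=None) -> pd.DataFrame:
        variables = list(variables) if variables is not None else [
            v for v in ENV_VARIABLES if v in self.frame.columns
        ]
        return self.frame[variables].astype(float)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a taxa x samples count table from TSV (canonical) or BIOM."""
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
        if frame.columns.duplicated().any() or frame.index.duplicated().any():
            raise TableFormatError(f"duplicate labels in {path}")
        try:
            values = frame.to_numpy(dtype=float)
        except ValueError as exc:
            raise TableFormatError(f"non-numeric cell in {path}: {exc}") from exc
        if np.any(np.mod(values, 1) != 0):
            raise ValidationError(f"non-integer counts in {path}")
        return CountTable(values.astype(np.int64), list(frame.index), list(frame.columns))
    if format == "biom":
        import biom

        table = biom.load_table(str(path))
        data = np.asarray(table.matrix_data.todense())
        return CountTable(
            data, list(table.ids(axis="observation")), list(table.ids(axis="sample"))
        )
    raise ParameterError(f"unknown count-table format {format!r}")


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyMap:
    """Two-column TSV (taxon_id, lineage string) -> TaxonomyMap."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["taxon_id", "lineage"], dtype=str)
    if frame["taxon_id"].duplicated().any():
        raise TableFormatError(f"duplicate taxon ids in {path}")
    return TaxonomyMap({row.taxon_id: parse_lineage(row.lineage) for row in frame.itertuples()})


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        for taxon_id, lineage in tax.lineages.items():
            joined = ";".join(
                pref + (name or "") for pref, name in zip(_RANK_PREFIXES, lineage)
            )
            fh.write(f"{taxon_id}\t{joined}\n")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# operations


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample to `depth` reads without replacement.

    Samples whose total is below `depth` are dropped with a warning; retained
    columns sum exactly to `depth`.  Uses the multivariate hypergeometric law,
    i.e. exact subsampling of reads without replacement.
    """
    if depth < 1:
        raise ParameterError("rarefaction depth must be >= 1")
    sums = table.sample_sums()
    keep = sums >= depth
    if not keep.any():
        raise InsufficientDataError(
            f"no sample reaches rarefaction depth {depth} (max total {sums.max()})"
        )
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    cols = []
    kept_ids = []
    for j, sample in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        cols.append(rng.multivariate_hypergeometric(table.counts[:, j], depth))
        kept_ids.append(sample)
    return CountTable(np.column_stack(cols), table.taxon_ids, kept_ids)


def aggregate_by_rank(table: CountTable, tax: TaxonomyMap, rank: str) -> CountTable:
    """Sum counts of taxa sharing a label at `rank`; unmapped taxa pool into
    "Unassigned".  Column sums are conserved exactly."""
    if rank not in RANKS:
        raise ParameterError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = [tax.rank_label(t, rank) or "Unassigned" for t in table.taxon_ids]
    frame = table.to_frame()
    frame.index = pd.Index(labels, name="taxon_id")
    agg = frame.groupby(level=0, sort=True).sum()
    return CountTable.from_frame(agg)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Counts -> per-sample proportions (columns sum to 1)."""
    sums = table.sample_sums()
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = [table.sample_ids[j] for j in zero]
        raise ValidationError(f"zero-sum sample(s), relative abundance undefined: {bad}")
    frame = table.to_frame().astype(float)
    return frame / sums
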