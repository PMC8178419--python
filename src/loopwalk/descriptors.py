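"""Amino-acid physicochemical descriptor tables and loop-variant encoding.

A :class:`DescriptorTable` holds a set of named physicochemical scales
(one real value per canonical amino acid, AAindex-style).  Residue triples
from a mutagenised loop are encoded position-major into fixed-length
feature vectors: with the packaged 13-descriptor set and three loop
positions the encoding is 39-dimensional (13 descriptors x 3 positions).

The packaged table (:meth:`DescriptorTable.paper_set`) covers the thirteen
properties used for loop-mutant discrimination modelling: isoelectric
point, normalized van der Waals volume, alpha-helix and beta-strand
indices for beta-proteins, side-chain contribution to protein stability,
a knowledge-based atom-atom potential stability scale, hydropathy,
normalized turn frequency, beta-strand and alpha-helical free energies,
polarity, a side-chain interaction parameter, and amino-acid distribution.
Rows whose citation field says "synthetic stand-in scale" are constructed
profiles matching the qualitative behaviour of the named property, not
transcriptions of a published index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

#: Canonical one-letter codes in AAindex I-record order.
ALPHABET: str = "ARNDCQEGHILKMFPSTWYV"

#: Order of amino acids on the two value lines of an AAindex1 I-record.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


class DescriptorError(ValueError):
    """Raised for malformed, incomplete or duplicated descriptor data."""


class EncodingError(ValueError):
    """Raised when a residue triple cannot be encoded (non-canonical letter)."""


@dataclass(frozen=True)
class DescriptorTable:
    """A matrix of physicochemical scales: descriptors x 20 amino acids.

    Parameters
    ----------
    values
        DataFrame indexed by descriptor_id with exactly the 20 canonical
        amino-acid columns in :data:`ALPHABET` order; no missing values.
    descriptions, citations
        Free-text metadata aligned with ``values.index``.
    """

    values: pd.DataFrame
    descriptions: pd.Series = field(default=None)  # type: ignore[assignment]
    citations: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = self.values
        if list(vals.columns) != list(ALPHABET):
            missing = sorted(set(ALPHABET) - set(vals.columns))
            if missing:
                raise DescriptorError(
                    f"descriptor table is missing amino-acid columns {missing}"
                )
            # reorder into the fixed alphabet order regardless of source order
            object.__setattr__(self, "values", vals.loc[:, list(ALPHABET)])
            vals = self.values
        if vals.index.has_duplicates:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise DescriptorError(f"duplicate descriptor_id(s): {dupes}")
        if vals.isna().any().any():
            bad = vals.index[vals.isna().any(axis=1)].tolist()
            raise DescriptorError(f"missing values in descriptor(s): {bad}")
        if self.descriptions is None:
            object.__setattr__(
                self, "descriptions", pd.Series("", index=vals.index)
            )
        if self.citations is None:
            object.__setattr__(self, "citations", pd.Series("", index=vals.index))

    # ------------------------------------------------------------------ #
    @property
    def descriptor_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_descriptors(self) -> int:
        return len(self.values)

    def subset(self, ids: Sequence[str]) -> "DescriptorTable":
        return DescriptorTable(
            self.values.loc[list(ids)],
            self.descriptions.loc[list(ids)],
            self.citations.loc[list(ids)],
        )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorTable":
        """Load from a CSV with header ``descriptor_id,description,citation,A,R,...,V``."""
        df = pd.read_csv(path)
        required = {"descriptor_id", "description", "citation", *ALPHABET}
        missing = required - set(df.columns)
        if missing:
            raise DescriptorError(f"descriptor CSV lacks column(s) {sorted(missing)}")
        df = df.set_index("descriptor_id")
        return cls(
            df[list(ALPHABET)].astype(float),
            df["description"],
            df["citation"],
        )

    @classmethod
    def from_aaindex1(cls, source: str | Path) -> "DescriptorTable":
        """Parse an AAindex1 flat file (H/D/R/I record structure).

        ``source`` may be a path or the flat-file text itself.  Records with
        an ``NA`` value for any amino acid are rejected with an error naming
        the affected letters.
        """
        text = source if isinstance(source, str) and "\n" in source else Path(source).read_text()
        rows, descs = {}, {}
        for chunk in text.split("//"):
            chunk = chunk.strip("\n ")
            if not chunk:
                continue
            rows_, desc = _parse_aaindex_record(chunk)
            acc, vals = rows_
            if acc in rows:
                raise DescriptorError(f"duplicate descriptor_id(s): ['{acc}']")
            rows[acc] = vals
            descs[acc] = desc
        if not rows:
            raise DescriptorError("no AAindex1 records found in source")
        values = pd.DataFrame.from_dict(rows, orient="index", columns=list(ALPHABET))
        return cls(values, pd.Series(descs), pd.Series("AAindex1", index=values.index))

    @classmethod
    def paper_set(cls) -> "DescriptorTable":
        """The packaged 13-descriptor table used for loop-mutant modelling.

        The table object is cached; repeated calls return the same instance.
        """
        global _PAPER_SET
        if _PAPER_SET is None:
            with resources.as_file(
                resources.files("loopwalk.data") / "descriptors13.csv"
            ) as path:
                _PAPER_SET = cls.from_csv(path)
        return _PAPER_SET


_PAPER_SET: "DescriptorTable | None" = None


def _parse_aaindex_record(chunk: str) -> tuple[tuple[str, dict[str, float]], str]:
    accession, description = "", ""
    value_lines: list[str] = []
    in_values = False
    for line in chunk.splitlines():
        tag, _, rest = line.partition(" ")
        if tag == "H":
            accession = rest.strip()
            in_values = False
        elif tag == "D":
            description = rest.strip()
            in_values = False
        elif tag == "I":
            in_values = True  # header line "I  A/L  R/K ..."; values follow
        elif in_values and line.startswith((" ", "\t")):
            value_lines.append(line)
        else:
            in_values = False
    if not accession:
        raise DescriptorError("AAindex1 record without an H (accession) line")
    tokens = " ".join(value_lines).split()
    if len(tokens) != 20:
        raise DescriptorError(
            f"AAindex1 record {accession}: expected 20 values, found {len(tokens)}"
        )
    order = _AAINDEX_ROW1 + _AAINDEX_ROW2
    missing = [aa for aa, tok in zip(order, tokens) if tok.upper() == "NA"]
    if missing:
        raise DescriptorError(
            f"AAindex1 record {accession} has NA values for amino acid(s) {missing}"
        )
    vals = {aa: float(tok) for aa, tok in zip(order, tokens)}
    return (accession, vals), description


# ---------------------------------------------------------------------- #
# descriptor de-duplication by hierarchical clustering


def select_representative_descriptors(
    table: DescriptorTable, n_clusters: int
) -> DescriptorTable:
    """Pick one representative descriptor per correlation cluster.

    Descriptors are clustered by average-linkage hierarchical clustering on
    the distance ``1 - |Pearson r|`` between their 20-value rows, the tree is
    cut to ``n_clusters``, and each cluster contributes the member with the
    highest mean absolute correlation to its co-members (singletons return
    their sole member).  Absolute correlation is used because a scale and its
    negation carry identical information.

    Zero-variance descriptors are excluded (with a warning) before
    clustering.
    """
    vals = table.values.to_numpy(float)
    sds = vals.std(axis=1)
    constant = sds == 0
    if constant.any():
        dropped = [i for i, c in zip(table.descriptor_ids, constant) if c]
        warnings.warn(
            f"excluding zero-variance descriptor(s) {dropped} from clustering",
            stacklevel=2,
        )
    ids = [i for i, c in zip(table.descriptor_ids, constant) if not c]
    if n_clusters > len(ids):
        raise DescriptorError(
            f"n_clusters={n_clusters} exceeds the {len(ids)} usable descriptors"
        )
    if n_clusters < 1:
        raise DescriptorError("n_clusters must be >= 1")
    sub = vals[~constant]
    corr = np.corrcoef(sub)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrise fp noise
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    assignment = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")

    representatives: list[str] = []
    for label in np.unique(assignment):
        members = np.flatnonzero(assignment == label)
        if len(members) == 1:
            representatives.append(ids[members[0]])
            continue
        block = np.abs(corr[np.ix_(members, members)])
        mean_corr = (block.sum(axis=1) - 1.0) / (len(members) - 1)
        representatives.append(ids[members[int(np.argmax(mean_corr))]])
    # return in the original table order
    ordered = [i for i in table.descriptor_ids if i in set(representatives)]
    return table.subset(ordered)


# ---------------------------------------------------------------------- #
# encoding


def encode_variant(
    triple: str | Sequence[str], table: DescriptorTable
) -> np.ndarray:
    """Encode a residue triple as a position-major feature vector.

    The vector lays out all descriptors for position 1, then position 2,
    then position 3 (length ``n_positions * n_descriptors``; 39 for the
    packaged 13-descriptor set).  Encoding is a pure function of the triple.
    """
    letters = list(triple)
    for pos, letter in enumerate(letters, start=1):
        if letter not in ALPHABET:
            raise EncodingError(
                f"non-canonical amino acid {letter!r} at position {pos}"
            )
    vals = table.values
    return np.concatenate([vals[letter].to_numpy(float) for letter in letters])


def feature_names(
    table: DescriptorTable, n_positions: int = 3
) -> list[str]:
    """Position-major feature labels, e.g. ``p1:hydropathy``."""
    return [
        f"p{k}:{d}" for k in range(1, n_positions + 1) for d in table.descriptor_ids
    ]


def encode_library(
    triples: Iterable[str | Sequence[str]], table: DescriptorTable
) -> pd.DataFrame:
    """Encode many triples; rows indexed by the triple string.

    Vectorised but bit-identical to stacking :func:`encode_variant` rows.
    """
    triples = ["".join(t) for t in triples]
    if not triples:
        return pd.DataFrame(
            np.empty((0, 3 * table.n_descriptors)), columns=feature_names(table)
        )
    aa_index = {aa: i for i, aa in enumerate(ALPHABET)}
    idx = np.empty((len(triples), 3), dtype=int)
    for r, t in enumerate(triples):
        if len(t) != 3:
            raise EncodingError(f"expected a residue triple, got {t!r}")
        for pos, letter in enumerate(t):
            if letter not in aa_index:
                raise EncodingError(
                    f"non-canonical amino acid {letter!r} at position {pos + 1} "
                    f"in triple {t!r}"
                )
            idx[r, pos] = aa_index[letter]
    # columns of ``values`` are in ALPHABET order; take per-position blocks
    M = table.values.to_numpy(float).T  # 20 x n_descriptors
    mat = np.concatenate([M[idx[:, k]] for k in range(3)], axis=1)
    return pd.DataFrame(mat, index=triples, columns=feature_names(table))


# ---------------------------------------------------------------------- #
# standardization


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature mean and (population) standard deviation.

    Constant columns are flagged and standardize to zero rather than NaN;
    L1-penalised fits are scale-sensitive, so features are standardized
    before model fitting and the stored parameters re-applied to candidates.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of zero-variance columns

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]


def fit_scaler(matrix: np.ndarray) -> ScalerParams:
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scaler fitting requires a 2-D matrix with >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population convention (ddof=0)
    return ScalerParams(mean=mean, sd=sd, constant=sd == 0)


def apply_scaler(matrix: np.ndarray, params: ScalerParams) -> np.ndarray:
    X = np.asarray(matrix, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params.n_features:
        raise ValueError(
            f"matrix has {X.shape[1]} columns but scaler expects {params.n_features}"
        )
    denom = np.where(params.constant, 1.0, params.sd)
    out = (X - params.mean) / denom
    out[:, params.constant] = 0.0
    return out
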