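"""Domain containers and input handling.

Two containers drive everything downstream: :class:`BinaryMatrix`, a validated
subjects x columns 0/1 matrix with identifiers (used for both genotypes ``X``
and phenotypes ``Y``), and :class:`CollapsedData`, the lossless reduction that
merges subjects sharing an identical phenotype profile into one weighted
pseudo-subject.  The collapse preserves every count the association statistics
need, so all later optimisation can run on the (often far smaller) collapsed
input.

Files are plain TSV: header row of column ids, first column of subject ids,
body entries 0/1.  Missing values are not supported; any non-binary token is
an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinaryMatrix",
    "CollapsedData",
    "CNFPhenotype",
    "MatrixFormatError",
    "ValidationError",
    "read_binary_matrix",
    "write_binary_matrix",
    "collapse_subjects",
]


class MatrixFormatError(ValueError):
    """A file (or array) does not conform to the binary-matrix format."""


class ValidationError(ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


@dataclass(frozen=True)
class BinaryMatrix:
    """Subjects x columns 0/1 matrix with unique row and column identifiers.

    ``kind`` is purely informational ("genotype" or "phenotype"); the
    container is the same for both.
    """

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    kind: str = "genotype"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.int8)
        if values.ndim != 2:
            raise MatrixFormatError("matrix must be two-dimensional")
        bad = (values != 0) & (values != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"non-binary entry at row {self.row_ids[i]!r}, "
                f"column {self.col_ids[j]!r}"
            )
        if values.shape != (len(self.row_ids), len(self.col_ids)):
            raise MatrixFormatError("id lengths do not match matrix shape")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row (subject) identifiers")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValidationError("duplicate column identifiers")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(str(r) for r in self.row_ids))
        object.__setattr__(self, "col_ids", tuple(str(c) for c in self.col_ids))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def column(self, key: int | str) -> np.ndarray:
        """Return one column as an int8 vector, by index or identifier."""
        if isinstance(key, str):
            key = self.col_ids.index(key)
        return self.values[:, key]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinaryMatrix)
            and self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class CollapsedData:
    """Output of the subject-collapse preprocessor.

    Attributes
    ----------
    profiles
        U x P matrix of the distinct phenotype rows, in lexicographic order
        (first phenotype column most significant).
    carrier_counts
        U x N integer matrix; entry (i, j) is how many subjects with
        profile i carry variant j.
    multiplicity
        Length-U vector; how many subjects share each profile.
    subject_ids
        Per-profile tuples of the original subject identifiers (traceability
        aid; not needed by any computation).
    pheno_ids, snp_ids
        Column identifiers carried over from the inputs.
    """

    profiles: np.ndarray
    carrier_counts: np.ndarray
    multiplicity: np.ndarray
    pheno_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    subject_ids: tuple[tuple[str, ...], ...] = field(default=(), repr=False)

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_subjects(self) -> int:
        return int(self.multiplicity.sum())

    def validate(self) -> None:
        U, P = self.profiles.shape
        if self.multiplicity.shape != (U,) or self.carrier_counts.shape[0] != U:
            raise ValidationError("collapsed component shapes disagree")
        if (self.multiplicity <= 0).any():
            raise ValidationError("multiplicities must be positive")
        if ((self.carrier_counts < 0)
                | (self.carrier_counts > self.multiplicity[:, None])).any():
            raise ValidationError("carrier counts outside [0, multiplicity]")
        order = np.lexsort(self.profiles.T[::-1])
        if not np.array_equal(order, np.arange(U)):
            raise ValidationError("profiles not in lexicographic order")
        if U > 1 and (np.diff(self.profiles, axis=0) == 0).all(axis=1).any():
            raise ValidationError("duplicate profiles present")


@dataclass(frozen=True)
class CNFPhenotype:
    """A combined phenotype: AND of K clauses, each an OR of phenotype
    indices (at most L per clause).

    A subject has the combined phenotype iff, in every clause, they have at
    least one of the listed phenotypes.
    """

    clauses: tuple[frozenset[int], ...]

    def __post_init__(self):
        clauses = tuple(frozenset(int(j) for j in c) for c in self.clauses)
        if len(clauses) == 0:
            raise ValidationError("a CNF needs at least one clause")
        if any(len(c) == 0 for c in clauses):
            raise ValidationError("empty clause: the OR of nothing is undefined")
        object.__setattr__(self, "clauses", clauses)

    @property
    def K(self) -> int:
        return len(self.clauses)

    @property
    def max_clause_size(self) -> int:
        return max(len(c) for c in self.clauses)

    def check_indices(self, n_phenotypes: int) -> None:
        for c in self.clauses:
            for j in c:
                if not 0 <= j < n_phenotypes:
                    raise ValidationError(
                        f"phenotype index {j} outside [0, {n_phenotypes})"
                    )

    def canonical(self) -> "CNFPhenotype":
        """Stable form: indices sorted within clauses, clauses sorted."""
        ordered = sorted(tuple(sorted(c)) for c in set(self.clauses))
        return CNFPhenotype(tuple(frozenset(c) for c in ordered))

    def to_string(self, pheno_ids: tuple[str, ...] | None = None) -> str:
        def name(j):
            return pheno_ids[j] if pheno_ids is not None else str(j)

        parts = ["(" + "|".join(name(j) for j in sorted(c)) + ")"
                 for c in sorted(tuple(sorted(c)) for c in self.clauses)]
        return "&".join(parts)

    @staticmethod
    def from_string(text: str,
                    pheno_ids: tuple[str, ...] | None = None) -> "CNFPhenotype":
        clauses = []
        for part in text.split("&"):
            part = part.strip().strip("()")
            lits = [tok.strip() for tok in part.split("|") if tok.strip()]
            if pheno_ids is not None:
                idx = [pheno_ids.index(t) for t in lits]
            else:
                idx = [int(t) for t in lits]
            clauses.append(frozenset(idx))
        return CNFPhenotype(tuple(clauses))


def read_binary_matrix(path: str | Path, kind: str = "genotype") -> BinaryMatrix:
    """Read a TSV with a header row, a subject-id first column, and 0/1 body.

    Row order of the file is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=np.int8)
    body = df.to_numpy()
    for j in range(df.shape[1]):
        for i in range(df.shape[0]):
            tok = body[i, j]
            if tok == "0":
                values[i, j] = 0
            elif tok == "1":
                values[i, j] = 1
            else:
                raise MatrixFormatError(
                    f"{path}: non-binary entry {tok!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                )
    return BinaryMatrix(values, tuple(row_ids), tuple(col_ids), kind=kind)


def write_binary_matrix(matrix: BinaryMatrix, path: str | Path) -> None:
    """Write the matrix in the same TSV dialect `read_binary_matrix` accepts."""
    df = pd.DataFrame(matrix.values, index=list(matrix.row_ids),
                      columns=list(matrix.col_ids))
    df.index.name = "subject"
    df.to_csv(path, sep="\t")


def check_aligned(X: BinaryMatrix, Y: BinaryMatrix) -> None:
    """Genotype and phenotype matrices must cover the same subjects in order."""
    if X.row_ids != Y.row_ids:
        raise ValidationError(
            "genotype and phenotype matrices have different subject rows"
        )


def collapse_subjects(X: BinaryMatrix, Y: BinaryMatrix) -> CollapsedData:
    """Merge subjects with identical phenotype profiles, without loss.

    Sorts the rows of ``Y`` lexicographically, run-length-encodes the sorted
    rows into unique profiles with multiplicities, and sums the corresponding
    row blocks of ``X`` into per-profile carrier counts.  Every statistic
    that depends only on the 2x2 table of (combined phenotype, variant) is
    computable from the result: a CNF evaluated on profiles, weighted by
    multiplicity and carrier counts, yields the same (nu, nv, nuv).
    """
    check_aligned(X, Y)
    profiles, inverse, counts = np.unique(
        Y.values, axis=0, return_inverse=True, return_counts=True
    )
    inverse = inverse.ravel()
    U = profiles.shape[0]
    carrier = np.zeros((U, X.n_cols), dtype=np.int64)
    np.add.at(carrier, inverse, X.values.astype(np.int64))
    subject_ids = tuple(
        tuple(np.asarray(Y.row_ids)[inverse == u]) for u in range(U)
    )
    out = CollapsedData(
        profiles=profiles.astype(np.int8),
        carrier_counts=carrier,
        multiplicity=counts.astype(np.int64),
        pheno_ids=Y.col_ids,
        snp_ids=X.col_ids,
        subject_ids=subject_ids,
    )
    out.validate()
    return out


def uncollapsed(X: BinaryMatrix, Y: BinaryMatrix) -> CollapsedData:
    """View the raw matrices as trivially 'collapsed' data (one subject per
    profile row, original row order).  Used to build formulations without the
    preprocessing step, e.g. for size accounting and equivalence checks."""
    check_aligned(X, Y)
    return CollapsedData(
        profiles=Y.values,
        carrier_counts=X.values.astype(np.int64),
        multiplicity=np.ones(Y.n_subjects, dtype=np.int64),
        pheno_ids=Y.col_ids,
        snp_ids=X.col_ids,
        subject_ids=tuple((r,) for r in Y.row_ids),
    )
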