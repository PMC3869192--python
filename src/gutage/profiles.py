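"""Functional-profile tables, sample metadata, and annotation aggregation.

A *functional profile* is a samples x features table of non-negative
abundances, where a feature is a protein family (Pfam), a KEGG pathway, a
KEGG ortholog, or a Gene Ontology term, and each entry counts the distinct
non-redundant proteins of a metagenomic sample assigned to that feature.
This module reads and writes such tables, parses the tabular outputs of the
upstream homology searches (HMMER against Pfam, BLAST against UniProt), and
aggregates per-protein assignments into per-sample counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NAMESPACES = ("pfam", "kegg_pathway", "kegg_ko", "go")


class FormatError(ValueError):
    """A file does not conform to its expected tabular layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (e.g. negative count)."""


@dataclass
class FunctionalProfileMatrix:
    """Samples x features abundance table with a feature-namespace tag.

    ``data`` is a pandas DataFrame indexed by sample identifier with one
    column per feature identifier. Entries are non-negative reals: counts of
    distinct non-redundant proteins assigned to each feature — a measure of
    protein-family diversity within a sample, not of gene expression.
    """

    data: pd.DataFrame
    namespace: str = "pfam"

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValidationError(
                f"unknown feature namespace {self.namespace!r}; "
                f"expected one of {NAMESPACES}"
            )
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature identifiers: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if values.size and (np.isnan(values).any() or (values < 0).any()):
            raise ValidationError("abundance entries must be non-negative reals")

    # -- convenience views -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def restrict(self, feature_ids: Sequence[str]) -> "FunctionalProfileMatrix":
        """Column subset in the given order; unknown features are an error."""
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise ValidationError(f"features not in matrix: {missing[:5]}")
        return FunctionalProfileMatrix(self.data.loc[:, list(feature_ids)].copy(),
                                       self.namespace)

    def take_samples(self, sample_ids: Sequence[str]) -> "FunctionalProfileMatrix":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        return FunctionalProfileMatrix(self.data.loc[list(sample_ids)].copy(),
                                       self.namespace)


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata: host age in years, country, optional flags.

    ``ibd`` and ``obese`` are None when unknown (absence of the column does
    not imply a negative diagnosis).
    """

    sample_id: str
    age: int
    country: str
    ibd: bool | None = None
    obese: bool | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not (1 <= self.age <= 120):
            raise ValidationError(
                f"age {self.age} for sample {self.sample_id!r} outside [1, 120]"
            )


@dataclass(frozen=True)
class AnnotationHit:
    """One homology-search hit of a protein against a reference entry."""

    query_id: str
    target_id: str
    evalue: float
    score: float
    above_threshold: bool = True

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"negative e-value for query {self.query_id!r}")


# ---------------------------------------------------------------------------
# Abundance tables


def read_abundance_table(path: str | Path,
                         namespace: str = "pfam") -> FunctionalProfileMatrix:
    """Read a features-as-rows TSV abundance table into samples x features.

    The on-disk layout has feature identifiers in the first column and one
    column per sample. Missing cells are treated as zero.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected feature column plus >=1 sample column")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample identifiers {dupes}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message pass-through
        raise FormatError(f"{path}: {exc}") from exc
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate feature identifiers {dupes}")
    frame = frame.apply(pd.to_numeric, errors="coerce")
    # distinguish unparseable text (format) from genuinely missing (zero-fill)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = frame.isna() & raw.notna()
    if bad.to_numpy().any():
        raise FormatError(f"{path}: non-numeric abundance cells")
    frame = frame.fillna(0.0)
    if (frame.to_numpy(dtype=float) < 0).any():
        raise ValidationError(f"{path}: negative abundance cells")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return FunctionalProfileMatrix(frame.T, namespace=namespace)


def write_abundance_table(matrix: FunctionalProfileMatrix,
                          path: str | Path) -> None:
    """Write a profile matrix as a features-as-rows TSV (inverse of read)."""
    out = matrix.data.T
    out.index.name = "feature_id"
    out.to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# Metadata


_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_flag(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text in ("", "na", "nan", "none", "unknown"):
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise FormatError(f"cannot interpret flag value {value!r}")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata TSV (columns sample_id, age, country[, ibd, obese])."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "age", "country"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        try:
            age_f = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric age {row['age']!r}") from exc
        if age_f != int(age_f):
            raise ValidationError(f"{path}: non-integer age {row['age']!r}")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                age=int(age_f),
                country=str(row["country"]),
                ibd=_parse_flag(row.get("ibd")),
                obese=_parse_flag(row.get("obese")),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample_id values")
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "age": r.age,
                "country": r.country,
                "ibd": "" if r.ibd is None else int(r.ibd),
                "obese": "" if r.obese is None else int(r.obese),
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation outputs


def parse_pfam_hits(path: str | Path) -> list[AnnotationHit]:
    """Parse HMMER 3 tabular output (--tblout or --domtblout dialect).

    Assumes hmmscan orientation: queries are the sample's proteins, targets
    are Pfam models. Hits are recorded as given; filtering against the Pfam
    gathering threshold (GA) is the search tool's job (``--cut_ga``), since
    GA values live in the model files, not in the hit table. A protein may
    contribute zero, one or several hits.
    """
    path = Path(path)
    hits: list[AnnotationHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tok = line.split()
            try:
                if len(tok) >= 22:  # --domtblout: per-domain rows
                    target, acc, query = tok[0], tok[1], tok[3]
                    evalue, score = float(tok[6]), float(tok[7])
                elif len(tok) >= 18:  # --tblout: per-sequence rows
                    target, acc, query = tok[0], tok[1], tok[2]
                    evalue, score = float(tok[4]), float(tok[5])
                else:
                    raise ValueError("too few columns")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed HMMER line "
                                  f"({exc})") from exc
            target_id = acc if acc != "-" else target
            hits.append(AnnotationHit(query_id=query, target_id=target_id,
                                      evalue=evalue, score=score))
    return hits


def parse_blast_hits(path: str | Path) -> list[AnnotationHit]:
    """Parse 12-column BLAST tabular output (-outfmt 6)."""
    path = Path(path)
    hits: list[AnnotationHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tok = line.rstrip("\n").split("\t")
            if len(tok) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, "
                                  f"got {len(tok)}")
            try:
                evalue, score = float(tok[10]), float(tok[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric "
                                  f"field") from exc
            hits.append(AnnotationHit(query_id=tok[0], target_id=tok[1],
                                      evalue=evalue, score=score))
    return hits


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV mapping UniProt accession -> comma-separated GO IDs."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tok = line.rstrip("\n").split("\t")
            if len(tok) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            terms = {t.strip() for t in tok[1].split(",") if t.strip()}
            mapping.setdefault(tok[0], set()).update(terms)
    return mapping


def transfer_go_terms(blast_hits: Sequence[AnnotationHit],
                      go_map: Mapping[str, set[str]],
                      evalue_max: float = 1e-5) -> dict[str, set[str]]:
    """Transfer GO terms to each query from its best BLAST match.

    The best match is the hit with the smallest e-value (ties broken by
    highest bit score, then lexicographic target accession). Terms transfer
    only when the best match's e-value is <= ``evalue_max``; queries whose
    best match fails the threshold, or maps to no GO terms, are absent from
    the result.
    """
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be positive, got {evalue_max}")
    best: dict[str, AnnotationHit] = {}
    for hit in blast_hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            continue
        key_new = (hit.evalue, -hit.score, hit.target_id)
        key_cur = (cur.evalue, -cur.score, cur.target_id)
        if key_new < key_cur:
            best[hit.query_id] = hit
    out: dict[str, set[str]] = {}
    for query, hit in best.items():
        if hit.evalue > evalue_max:
            continue
        terms = go_map.get(hit.target_id)
        if terms:
            out[query] = set(terms)
    return out


def counts_from_assignments(assignments: Mapping[str, set[str]],
                            sample_id: str,
                            namespace: str = "pfam") -> FunctionalProfileMatrix:
    """Aggregate per-protein feature assignments into one sample's counts.

    The count for feature *f* is the number of distinct queries (non-redundant
    proteins) whose assignment set contains *f* — diversity of proteins per
    family, not expression.
    """
    counts: dict[str, int] = {}
    for features in assignments.values():
        for f in features:
            counts[f] = counts.get(f, 0) + 1
    features = sorted(counts)
    frame = pd.DataFrame([[counts[f] for f in features]],
                         index=[sample_id], columns=features, dtype=float)
    return FunctionalProfileMatrix(frame, namespace=namespace)


def merge_profiles(parts: Sequence[FunctionalProfileMatrix]) -> FunctionalProfileMatrix:
    """Merge single-sample profiles over the union of features, zero-filled.

    Row order follows input order; feature order is the sorted union.
    """
    if not parts:
        raise ValueError("nothing to merge")
    namespace = parts[0].namespace
    if any(p.namespace != namespace for p in parts):
        raise ValidationError("cannot merge profiles from different namespaces")
    sample_ids = [s for p in parts for s in p.sample_ids]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample_id across merged parts")
    order: list[str] = []
    seen: set[str] = set()
    for p in parts:
        for f in p.feature_ids:
            if f not in seen:
                seen.add(f)
                order.append(f)
    merged = pd.concat([p.data for p in parts], axis=0).fillna(0.0)
    merged = merged.loc[:, order]
    return FunctionalProfileMatrix(merged, namespace=namespace)
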