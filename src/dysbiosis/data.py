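"""Count-table, metadata and clinical-table data model with TSV / BIOM-JSON IO.

The pipeline's universal input is a samples x taxa integer count table with a
ranked taxonomy lineage per taxon (QIIME-style ``k__...;p__...;...;g__...``
strings), a sample metadata table assigning each sample to a subject and a
site (``lesion`` or ``peri_lesion``), and an optional long-format clinical
endpoint table. All downstream paired statistics key off the
:class:`PairedDesign` built from the metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LESION = "lesion"
PERI_LESION = "peri_lesion"
SITES = (LESION, PERI_LESION)
SUBJECT_LEVEL = "subject_level"

#: rank prefixes in lineage strings, ordered kingdom -> genus
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed into the data model."""


@dataclass
class TaxonCountTable:
    """Samples x taxa non-negative integer counts plus per-taxon lineages.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows).
    taxon_ids : list of str
        Unique taxon identifiers (columns).
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer counts.
    lineages : dict
        Maps each taxon id to a ranked lineage string, possibly truncated
        before the genus rank.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    lineages: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dupes = sorted({t for t in self.taxon_ids if self.taxon_ids.count(t) > 1})
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.taxon_ids)})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [t for t in self.taxon_ids if t not in self.lineages]
        if missing:
            raise ValidationError(f"taxa without lineage: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def subset_samples(self, keep: list[str]) -> "TaxonCountTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return TaxonCountTable(
            sample_ids=list(keep),
            taxon_ids=list(self.taxon_ids),
            counts=self.counts[idx, :].copy(),
            lineages={t: self.lineages[t] for t in self.taxon_ids},
        )

    def subset_taxa(self, keep: list[str]) -> "TaxonCountTable":
        idx = [self.taxon_ids.index(t) for t in keep]
        return TaxonCountTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=list(keep),
            counts=self.counts[:, idx].copy(),
            lineages={t: self.lineages[t] for t in keep},
        )


@dataclass(frozen=True)
class SampleMeta:
    """One row of sample metadata: sample -> (subject, site)."""

    sample_id: str
    subject_id: str
    site: str

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(
                f"sample {self.sample_id!r}: site {self.site!r} not in {SITES}"
            )


@dataclass
class PairedDesign:
    """Subject-indexed (lesion sample, peri-lesion sample) pairs.

    ``rejects`` lists (subject_id, reason) for subjects that could not be
    paired; they are reported, never silently dropped.
    """

    pairs: list[tuple[str, str, str]]
    rejects: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def subjects(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def lesion_samples(self) -> list[str]:
        return [p[1] for p in self.pairs]

    @property
    def peri_samples(self) -> list[str]:
        return [p[2] for p in self.pairs]


@dataclass
class ClinicalTable:
    """Long-format clinical endpoints: (subject, endpoint, site, value).

    ``site`` is ``lesion``, ``peri_lesion`` or ``subject_level`` (e.g. mMASI,
    which is scored once per subject).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "endpoint", "site", "value"}
        if not required.issubset(self.df.columns):
            raise ValidationError(
                f"clinical table must have columns {sorted(required)}"
            )
        bad_site = set(self.df["site"]) - {*SITES, SUBJECT_LEVEL}
        if bad_site:
            raise ValidationError(f"unknown clinical site values: {sorted(bad_site)}")
        key = self.df[["subject_id", "endpoint", "site"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].values.tolist()
            raise ValidationError(f"duplicate clinical rows: {dupes[:5]}")

    def endpoints(self) -> list[str]:
        return sorted(self.df["endpoint"].unique())

    def subject_values(self, endpoint: str, site: str) -> pd.Series:
        sub = self.df[(self.df["endpoint"] == endpoint) & (self.df["site"] == site)]
        return sub.set_index("subject_id")["value"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(
    path,
    format: str = "tsv",
    known_sample_ids: list[str] | None = None,
) -> TaxonCountTable:
    """Read a count table from TSV or BIOM v1 ("rich" JSON) format.

    The TSV dialect has taxon ids in the first column and sample ids in the
    header row; an optional trailing ``taxonomy`` column carries lineages.
    If ``known_sample_ids`` is given and matches the first column instead,
    a samples-as-rows orientation is detected and transposed. The returned
    table is always samples x taxa.
    """
    if format == "tsv":
        return _read_tsv(path, known_sample_ids)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format {format!r}")


def _read_tsv(path, known_sample_ids=None) -> TaxonCountTable:
    with open(path) as fh:
        raw_header = fh.readline().rstrip("\n").split("\t")
    if len(set(raw_header)) != len(raw_header):
        dupes = sorted({h for h in raw_header if raw_header.count(h) > 1})
        raise ValidationError(f"{path}: duplicate sample header entries {dupes}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least one id column and one data column")
    id_col = df.columns[0]
    row_ids = df[id_col].tolist()
    if len(set(row_ids)) != len(row_ids):
        dupes = sorted({r for r in row_ids if row_ids.count(r) > 1})
        raise ValidationError(f"{path}: duplicate row ids {dupes}")
    header = list(df.columns[1:])
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{path}: duplicate sample header entries {dupes}")

    lineages = {}
    if header and header[-1].lower() in ("taxonomy", "lineage"):
        lin_col = header.pop()
        lineages = dict(zip(row_ids, df[lin_col].fillna("").tolist()))
        df = df.drop(columns=[lin_col])

    mat = np.empty((len(row_ids), len(header)), dtype=np.int64)
    for j, col in enumerate(header):
        for i, cell in enumerate(df[col].tolist()):
            try:
                val = int(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-integer cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col!r}"
                ) from None
            mat[i, j] = val

    samples_as_rows = known_sample_ids is not None and set(row_ids) <= set(
        known_sample_ids
    )
    if samples_as_rows:
        sample_ids, taxon_ids, counts = row_ids, header, mat
    else:
        sample_ids, taxon_ids, counts = header, row_ids, mat.T
    if not lineages:
        lineages = {t: t for t in taxon_ids}
    else:
        lineages = {t: lineages.get(t, "") or t for t in taxon_ids}
    return TaxonCountTable(sample_ids, taxon_ids, counts, lineages)


def write_count_table(table: TaxonCountTable, path, format: str = "tsv") -> None:
    """Write a count table in the TSV (taxa-as-rows) or BIOM v1 JSON dialect."""
    if format == "tsv":
        df = pd.DataFrame(
            table.counts.T, index=table.taxon_ids, columns=table.sample_ids
        )
        df.insert(len(df.columns), "taxonomy", [table.lineages[t] for t in table.taxon_ids])
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t")
    elif format == "biom_json":
        nz = np.nonzero(table.counts.T)
        data = [
            [int(i), int(j), int(table.counts.T[i, j])] for i, j in zip(*nz)
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "dysbiosis",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [
                {
                    "id": t,
                    "metadata": {"taxonomy": table.lineages[t].split(";")},
                }
                for t in table.taxon_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)
    else:
        raise ValueError(f"unknown count-table format {format!r}")


def _read_biom_json(path) -> TaxonCountTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = doc["shape"]
        matrix_type = doc.get("matrix_type", "sparse")
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: not a BIOM v1 JSON document ({exc})") from None
    if shape != [len(taxon_ids), len(sample_ids)]:
        raise ValidationError(f"{path}: shape {shape} inconsistent with row/column lists")
    mat = np.zeros((len(taxon_ids), len(sample_ids)), dtype=np.int64)
    if matrix_type == "sparse":
        for i, j, v in doc["data"]:
            if v != int(v):
                raise ParseError(f"{path}: non-integer value {v} at ({i},{j})")
            mat[i, j] = int(v)
    else:
        mat[:, :] = np.asarray(doc["data"], dtype=np.int64)
    lineages = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        lineages[r["id"]] = ";".join(tax) if tax else r["id"]
    return TaxonCountTable(sample_ids, taxon_ids, mat.T, lineages)


def read_sample_meta(path) -> list[SampleMeta]:
    """Read sample metadata TSV with columns sample_id, subject_id, site."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "site"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: metadata must have columns {sorted(required)}")
    metas = [
        SampleMeta(r.sample_id, r.subject_id, r.site) for r in df.itertuples()
    ]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample ids in metadata: {dupes}")
    return metas


def write_sample_meta(metas: list[SampleMeta], path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.subject_id, m.site) for m in metas],
        columns=["sample_id", "subject_id", "site"],
    ).to_csv(path, sep="\t", index=False)


def read_clinical_table(path) -> ClinicalTable:
    """Read a long-format clinical TSV (subject_id, endpoint, site, value)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str, "endpoint": str, "site": str}
    )
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.df.to_csv(path, sep="\t", index=False)


def check_meta_coverage(table: TaxonCountTable, metas: list[SampleMeta]) -> None:
    """Every sample in the count table must have exactly one metadata row."""
    meta_ids = {m.sample_id for m in metas}
    missing = [s for s in table.sample_ids if s not in meta_ids]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")


# ---------------------------------------------------------------------------
# genus agglomeration
# ---------------------------------------------------------------------------

def genus_label(lineage: str) -> str:
    """Collapse a ranked lineage string to its genus label.

    A resolved genus rank (``g__Xyz``) maps to ``Xyz``. A lineage truncated
    above the genus maps to a placeholder named by its deepest resolved rank,
    e.g. ``o__Lactobacillales_unresolved`` for a lineage ending at the order
    Lactobacillales; an empty lineage maps to ``unclassified``. Lineages with
    no rank prefixes at all are taken to be genus names already.
    """
    lineage = (lineage or "").strip()
    if not lineage:
        return "unclassified"
    parts = [p.strip() for p in lineage.split(";") if p.strip()]
    if not parts:
        return "unclassified"
    if not any(p[:3] in RANK_PREFIXES for p in parts):
        return parts[-1]
    deepest = None
    for p in parts:
        prefix, rest = p[:3], p[3:]
        if prefix in RANK_PREFIXES and rest:
            deepest = p
    if deepest is None:
        return "unclassified"
    if deepest.startswith("g__"):
        return deepest[3:]
    return f"{deepest}_unresolved"


def agglomerate_to_genus(table: TaxonCountTable) -> TaxonCountTable:
    """Sum OTU counts sharing a genus label into one row per genus.

    Per-sample totals are conserved exactly. OTUs whose lineage stops above
    the genus rank collapse to a deepest-rank placeholder (e.g. an OTU
    resolved only to the order Lactobacillales becomes
    ``o__Lactobacillales_unresolved``); empty lineages go to ``unclassified``
    and are logged.
    """
    labels = {}
    for t in table.taxon_ids:
        lab = genus_label(table.lineages[t])
        if lab == "unclassified":
            log.warning("taxon %r has empty/unresolvable lineage; routed to 'unclassified'", t)
        labels[t] = lab
    genera = sorted(set(labels.values()))
    gidx = {g: k for k, g in enumerate(genera)}
    out = np.zeros((table.n_samples, len(genera)), dtype=np.int64)
    glineage: dict[str, str] = {}
    for j, t in enumerate(table.taxon_ids):
        g = labels[t]
        out[:, gidx[g]] += table.counts[:, j]
        lineage = table.lineages[t]
        # keep the (truncated) lineage of the first contributing OTU
        glineage.setdefault(g, lineage)
    return TaxonCountTable(list(table.sample_ids), genera, out, glineage)


# ---------------------------------------------------------------------------
# paired design
# ---------------------------------------------------------------------------

def build_paired_design(metas: list[SampleMeta]) -> PairedDesign:
    """Pair each subject's lesion and peri-lesion sample.

    Subjects with a missing site or replicate samples of one site go to the
    rejects list with a reason. Zero complete pairs is a hard error.
    """
    by_subject: dict[str, dict[str, list[str]]] = {}
    for m in metas:
        by_subject.setdefault(m.subject_id, {LESION: [], PERI_LESION: []})[
            m.site
        ].append(m.sample_id)
    pairs, rejects = [], []
    for subject in sorted(by_subject):
        les = by_subject[subject][LESION]
        per = by_subject[subject][PERI_LESION]
        if len(les) == 1 and len(per) == 1:
            pairs.append((subject, les[0], per[0]))
        else:
            rejects.append(
                (subject, f"{len(les)} lesion / {len(per)} peri_lesion samples")
            )
    if not pairs:
        raise ValidationError("no subject has a complete lesion/peri-lesion pair")
    if rejects:
        log.warning("%d subject(s) rejected from pairing: %s", len(rejects), rejects)
    return PairedDesign(pairs=pairs, rejects=rejects)
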