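"""Reading, validation and tidy-table output of clonotype repertoires.

Input is an AIRR Rearrangement TSV dialect (one row per nucleotide-level
clonotype) plus a sample metadata TSV mapping ``sample_id`` to donor,
replicate, sorted-subset label and sorted-cell count.  Clonotype identity at
the nucleotide level is the tuple (junction, v_call, j_call); ``d_call`` is
informative only.

All outputs are tidy TSVs with a stable column order, deterministic row
order and '.' decimal separator, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "Clonotype",
    "RepertoireSample",
    "RepertoireIOError",
    "SchemaError",
    "MetadataJoinError",
    "read_repertoire",
    "write_repertoire",
    "filter_singletons",
    "filter_singletons_donor_pooled",
    "write_table",
    "is_productive",
]

#: AIRR-standard rearrangement columns emitted by :func:`write_repertoire`.
AIRR_COLUMNS = [
    "sample_id",
    "junction",
    "junction_aa",
    "v_call",
    "d_call",
    "j_call",
    "duplicate_count",
    "productive",
]

METADATA_COLUMNS = ["sample_id", "donor_id", "replicate_id", "subset_label", "sorted_cell_count"]


class RepertoireIOError(ValueError):
    """Base class for repertoire input errors."""


class SchemaError(RepertoireIOError):
    """Mandatory columns missing from an input table."""


class MetadataJoinError(RepertoireIOError):
    """A sample present in the rearrangement table is absent from metadata."""


def is_productive(junction_nt: str, junction_aa: str) -> bool:
    """In-frame, stop-free, translation-consistent, C...F/W-anchored record."""
    if not junction_nt or not junction_aa:
        return False
    if len(junction_nt) % 3 != 0:
        return False
    aa = str(Seq(junction_nt).translate())
    if "*" in aa or aa != junction_aa:
        return False
    return junction_aa.startswith("C") and junction_aa.endswith(("F", "W"))


@dataclass(frozen=True)
class Clonotype:
    """One nucleotide-level rearrangement record in one sample."""

    junction_nt: str
    junction_aa: str
    v_call: str
    j_call: str
    read_count: int
    sample_id: str
    donor_id: str
    replicate_id: str
    subset_label: str
    d_call: str = ""
    productive: bool = True

    def __post_init__(self):
        if self.read_count < 1:
            raise RepertoireIOError(
                f"read_count must be >= 1, got {self.read_count} for {self.junction_nt!r}"
            )

    @property
    def nucleotype_key(self) -> tuple[str, str, str]:
        return (self.junction_nt, self.v_call, self.j_call)


@dataclass(frozen=True)
class RepertoireSample:
    """One sorted, sequenced sample: its clonotype set and sort metadata."""

    sample_id: str
    donor_id: str
    replicate_id: str
    subset_label: str
    sorted_cell_count: int
    clonotypes: tuple[Clonotype, ...] = field(default_factory=tuple)

    @property
    def total_reads(self) -> int:
        # Always recomputed, never trusted from input.
        return sum(c.read_count for c in self.clonotypes)

    def __len__(self) -> int:
        return len(self.clonotypes)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def read_repertoire(
    table_path: str | Path,
    metadata_path: str | Path,
    count_column: str = "duplicate_count",
) -> list[RepertoireSample]:
    """Read and validate clonotype tables against their sample metadata.

    Rows with an empty junction or a non-positive count are rejected and
    reported (logged per row category); nonproductive rows are flagged and
    retained.  Returns one :class:`RepertoireSample` per metadata sample,
    sorted by sample_id.
    """
    table = pd.read_csv(table_path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    _require_columns(table, ["sample_id", "junction", "junction_aa", "v_call", "j_call", count_column], "rearrangement table")
    _require_columns(meta, METADATA_COLUMNS, "metadata table")
    if meta["sample_id"].duplicated().any():
        dup = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise MetadataJoinError(f"duplicate sample_id in metadata: {dup}")
    meta_map = meta.set_index("sample_id").to_dict("index")
    key = meta[["donor_id", "replicate_id", "subset_label"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise MetadataJoinError("(donor_id, replicate_id, subset_label) not unique across samples")

    unknown = sorted(set(table["sample_id"]) - set(meta_map))
    if unknown:
        raise MetadataJoinError(f"sample(s) in rearrangement table absent from metadata: {unknown}")

    rejected = {"empty_junction": 0, "bad_count": 0}
    nonproductive = 0
    per_sample: dict[str, list[Clonotype]] = {sid: [] for sid in meta_map}
    for row in table.itertuples(index=False):
        jnt = getattr(row, "junction").upper()
        jaa = getattr(row, "junction_aa").upper()
        if not jnt:
            rejected["empty_junction"] += 1
            continue
        try:
            count = int(getattr(row, count_column))
        except ValueError:
            count = 0
        if count < 1:
            rejected["bad_count"] += 1
            continue
        m = meta_map[row.sample_id]
        productive = is_productive(jnt, jaa)
        if not productive:
            nonproductive += 1
        per_sample[row.sample_id].append(
            Clonotype(
                junction_nt=jnt,
                junction_aa=jaa,
                v_call=row.v_call,
                j_call=row.j_call,
                d_call=getattr(row, "d_call", ""),
                read_count=count,
                sample_id=row.sample_id,
                donor_id=m["donor_id"],
                replicate_id=m["replicate_id"],
                subset_label=m["subset_label"],
                productive=productive,
            )
        )
    if any(rejected.values()):
        log.warning("rejected rows: %s", rejected)
    if nonproductive:
        log.info("%d nonproductive rows flagged and retained", nonproductive)

    samples = []
    for sid in sorted(meta_map):
        m = meta_map[sid]
        samples.append(
            RepertoireSample(
                sample_id=sid,
                donor_id=m["donor_id"],
                replicate_id=m["replicate_id"],
                subset_label=m["subset_label"],
                sorted_cell_count=int(m["sorted_cell_count"]),
                clonotypes=tuple(
                    sorted(per_sample[sid], key=lambda c: (c.junction_nt, c.v_call, c.j_call))
                ),
            )
        )
    return samples


def filter_singletons(sample: RepertoireSample) -> RepertoireSample:
    """Drop clonotypes seen with a single read (retain read_count >= 2).

    Applied per sample before every frequency computation.  Idempotent; the
    input sample is never mutated.  An empty result is legal and logged.
    """
    kept = tuple(c for c in sample.clonotypes if c.read_count >= 2)
    if not kept and sample.clonotypes:
        log.warning("sample %s: all clonotypes were singletons", sample.sample_id)
    return replace(sample, clonotypes=kept)


def filter_singletons_donor_pooled(
    samples: Sequence[RepertoireSample],
) -> list[RepertoireSample]:
    """Variant singleton filter pooling read counts across a donor's samples.

    Retains, in every sample, the clonotypes whose summed read count over
    all samples of the same donor is at least 2.  The per-sample filter
    (:func:`filter_singletons`) is the default; this variant is exposed for
    sensitivity analyses of the filtering scope.
    """
    pooled: dict[tuple, int] = {}
    for s in samples:
        for c in s.clonotypes:
            key = (s.donor_id, *c.nucleotype_key)
            pooled[key] = pooled.get(key, 0) + c.read_count
    return [
        replace(
            s,
            clonotypes=tuple(
                c for c in s.clonotypes if pooled[(s.donor_id, *c.nucleotype_key)] >= 2
            ),
        )
        for s in samples
    ]


def _clonotype_rows(samples: Iterable[RepertoireSample]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "junction": c.junction_nt,
            "junction_aa": c.junction_aa,
            "v_call": c.v_call,
            "d_call": c.d_call,
            "j_call": c.j_call,
            "duplicate_count": c.read_count,
            "productive": "T" if c.productive else "F",
        }
        for s in samples
        for c in s.clonotypes
    ]
    df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    return df.sort_values(["sample_id", "junction", "v_call", "j_call"], kind="stable")


def write_repertoire(
    samples: Sequence[RepertoireSample],
    table_path: str | Path,
    metadata_path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write samples as an AIRR-style rearrangement TSV + metadata TSV."""
    write_table(_clonotype_rows(samples), table_path, header_comment=header_comment)
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "donor_id": s.donor_id,
                "replicate_id": s.replicate_id,
                "subset_label": s.subset_label,
                "sorted_cell_count": s.sorted_cell_count,
            }
            for s in samples
        ],
        columns=METADATA_COLUMNS,
    ).sort_values("sample_id", kind="stable")
    write_table(meta, metadata_path, header_comment=header_comment)


def write_table(
    records: pd.DataFrame | Iterable,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write records as a tidy, deterministic TSV.

    Accepts a DataFrame or an iterable of dataclass instances.  Rows are
    sorted by ``sort_by`` (default: all columns, left to right) so repeated
    runs produce byte-identical files; an empty record set yields a
    header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if records and dataclasses.is_dataclass(records[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        else:
            df = pd.DataFrame(records)
    if len(df) and sort_by is None:
        sort_by = list(df.columns)
    if len(df) and sort_by:
        df = df.sort_values(list(sort_by), kind="stable")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
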