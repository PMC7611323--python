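"""Per-sample read-start records -> site x sample 5hmC count matrix + filtering.

An RRHP read is informative when it begins at a CCGG site; a sample's 5hmC
level at a site is simply the number of reads starting there.  Counts are
assembled by tallying identical (chrom, position, strand) keys per sample.

Two sequential filters guard against false 5hmC sites:

1. **group-presence filter** — a site is removed when at least
   ``min_failing_groups`` tissue groups have (by default) zero counts across
   all their replicates;
2. **global-median filter** — the median of all count cells of the matrix
   surviving filter 1 is taken, and a site is removed when at least one tissue
   has *all* of its replicates <= that median.

Filtering only drops rows; counts are never modified.  Library sizes are the
column sums of whichever matrix they are asked of.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome_io import CcggSite

__all__ = [
    "ReadStartRecord",
    "SampleInfo",
    "CountMatrix",
    "FilterReport",
    "parse_read_starts",
    "write_read_starts",
    "build_count_matrix",
    "group_presence_filter",
    "global_median_filter",
    "apply_two_stage_filter",
    "read_count_matrix_tsv",
    "write_count_matrix_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
]


class ReadStartRecord(NamedTuple):
    chrom: str
    position: int
    strand: str


class SampleInfo(NamedTuple):
    sample_id: str
    tissue: str
    replicate: int


@dataclass
class CountMatrix:
    """Sites x samples non-negative integer counts with sample metadata.

    ``counts`` is a DataFrame indexed by site keys (chrom, position, strand)
    tuples, with one column per sample_id, rows sorted by site key.
    """

    counts: pd.DataFrame
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError("count matrix columns do not match sample sheet order")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        pairs = [(s.tissue, s.replicate) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (tissue, replicate) pair")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def sites(self) -> list[tuple[str, int, str]]:
        return list(self.counts.index)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.tissue not in seen:
                seen.append(s.tissue)
        return seen

    def columns_for(self, tissue: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.tissue == tissue]

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        keep = [s for s in self.samples if s.tissue == tissue]
        if not keep:
            raise KeyError(f"no samples for tissue {tissue!r}")
        return CountMatrix(self.counts[[s.sample_id for s in keep]].copy(), keep)

    def drop_sites(self, keys: Iterable[tuple]) -> "CountMatrix":
        drop = set(keys)
        keep_mask = [k not in drop for k in self.counts.index]
        return CountMatrix(self.counts.loc[keep_mask].copy(), list(self.samples))


@dataclass
class FilterReport:
    """Accounting of the two-stage filter; tallies reconcile exactly."""

    n_input_sites: int
    n_removed_group_filter: int
    n_removed_median_filter: int
    global_median: float | None
    n_retained: int

    def __post_init__(self) -> None:
        total = self.n_removed_group_filter + self.n_removed_median_filter + self.n_retained
        if total != self.n_input_sites:
            raise ValueError(
                f"filter report does not reconcile: {self.n_input_sites} != {total}"
            )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def parse_read_starts(path: str | Path) -> list[ReadStartRecord]:
    """Parse a whitespace/tab-delimited (chrom, position, strand) file."""
    records: list[ReadStartRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            chrom, pos, strand = parts
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: strand {strand!r} not in {{+,-}}")
            try:
                position = int(pos)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position {pos!r}") from None
            if position < 1:
                raise ValueError(f"{path}:{lineno}: position {position} < 1")
            records.append(ReadStartRecord(chrom, position, strand))
    return records


def write_read_starts(records: Iterable[ReadStartRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.strand}\n")


def build_count_matrix(
    records_by_sample: dict[str, Sequence[ReadStartRecord]],
    samples: Sequence[SampleInfo],
    catalog: Sequence[CcggSite] | None = None,
) -> tuple[CountMatrix, dict]:
    """Tally read-start records into a site x sample count matrix.

    Cell (s, j) is the number of records of sample j at site key s.  When a
    catalogue is supplied, records at non-catalogue keys are dropped (tallied
    in the report).  Sites observed in no sample are excluded.  Returns the
    matrix and a small report dict.
    """
    ids = [s.sample_id for s in samples]
    if set(records_by_sample) != set(ids):
        raise ValueError("record collections do not match the sample sheet one-to-one")
    allowed = None
    if catalog is not None:
        allowed = {(s.chrom, s.position, s.strand) for s in catalog}
    tallies: dict[str, dict[tuple, int]] = {}
    n_dropped = 0
    for sid in ids:
        tally: dict[tuple, int] = {}
        for rec in records_by_sample[sid]:
            key = (rec.chrom, rec.position, rec.strand)
            if allowed is not None and key not in allowed:
                n_dropped += 1
                continue
            tally[key] = tally.get(key, 0) + 1
        tallies[sid] = tally
    all_keys = sorted(set().union(*(t.keys() for t in tallies.values())) if tallies else [])
    data = np.zeros((len(all_keys), len(ids)), dtype=np.int64)
    key_index = {k: i for i, k in enumerate(all_keys)}
    for j, sid in enumerate(ids):
        for key, n in tallies[sid].items():
            data[key_index[key], j] = n
    counts = pd.DataFrame(data, index=pd.Index(all_keys, tupleize_cols=False), columns=ids)
    report = {"n_records_dropped_off_catalog": n_dropped, "n_sites": len(all_keys)}
    return CountMatrix(counts, list(samples)), report


def _group_matrices(matrix: CountMatrix) -> dict[str, np.ndarray]:
    return {
        t: matrix.counts[matrix.columns_for(t)].to_numpy() for t in matrix.tissues
    }


def group_presence_filter(
    matrix: CountMatrix,
    group_threshold: int = 1,
    min_failing_groups: int = 2,
    group_stat: str = "sum",
) -> tuple[CountMatrix, list[tuple]]:
    """Remove sites detected in too few tissue groups.

    A tissue group *fails* at a site when its ``group_stat`` (sum or max of
    the replicates' counts) is below ``group_threshold``; the site is removed
    when at least ``min_failing_groups`` groups fail.  With the defaults
    (sum < 1, >= 2 of 3 groups) a site must be detected in at least two
    tissues to survive.
    """
    tissues = matrix.tissues
    if min_failing_groups > len(tissues):
        raise ValueError(
            f"min_failing_groups={min_failing_groups} exceeds the {len(tissues)} tissue groups"
        )
    if group_stat not in ("sum", "max"):
        raise ValueError(f"group_stat must be 'sum' or 'max', got {group_stat!r}")
    stat = np.sum if group_stat == "sum" else np.max
    failing = np.zeros(matrix.n_sites, dtype=int)
    for arr in _group_matrices(matrix).values():
        failing += stat(arr, axis=1) < group_threshold
    remove_mask = failing >= min_failing_groups
    removed = [k for k, r in zip(matrix.counts.index, remove_mask) if r]
    kept = CountMatrix(matrix.counts.loc[~remove_mask].copy(), list(matrix.samples))
    return kept, removed


def global_median_filter(
    matrix: CountMatrix,
    median_override: float | None = None,
    rule: str = "per_tissue_all",
    sample_quorum: int = 5,
) -> tuple[CountMatrix, list[tuple], FilterReport]:
    """Remove sites dominated by counts at or below the dataset median.

    The median ``m`` is taken over *all* count cells of the input matrix
    (or ``median_override``).  Under the default rule a site is removed when
    at least one tissue has ALL of its replicates <= m.  The alternative rule
    ``"any_samples"`` removes a site when >= ``sample_quorum`` of its samples
    (regardless of tissue) are <= m.
    """
    if matrix.n_sites == 0:
        report = FilterReport(0, 0, 0, None, 0)
        return matrix, [], report
    m = float(np.median(matrix.counts.to_numpy())) if median_override is None else float(median_override)
    if rule == "per_tissue_all":
        remove_mask = np.zeros(matrix.n_sites, dtype=bool)
        for arr in _group_matrices(matrix).values():
            remove_mask |= (arr <= m).all(axis=1)
    elif rule == "any_samples":
        remove_mask = (matrix.counts.to_numpy() <= m).sum(axis=1) >= sample_quorum
    else:
        raise ValueError(f"unknown rule {rule!r}")
    removed = [k for k, r in zip(matrix.counts.index, remove_mask) if r]
    kept = CountMatrix(matrix.counts.loc[~remove_mask].copy(), list(matrix.samples))
    report = FilterReport(
        n_input_sites=matrix.n_sites,
        n_removed_group_filter=0,
        n_removed_median_filter=len(removed),
        global_median=m,
        n_retained=kept.n_sites,
    )
    return kept, removed, report


def apply_two_stage_filter(
    matrix: CountMatrix,
    group_threshold: int = 1,
    min_failing_groups: int = 2,
    group_stat: str = "sum",
    median_override: float | None = None,
    median_rule: str = "per_tissue_all",
    sample_quorum: int = 5,
) -> tuple[CountMatrix, FilterReport]:
    """Filter 1 then filter 2; the median is that of the post-filter-1 matrix."""
    after1, removed1 = group_presence_filter(
        matrix, group_threshold=group_threshold,
        min_failing_groups=min_failing_groups, group_stat=group_stat,
    )
    after2, removed2, rep2 = global_median_filter(
        after1, median_override=median_override, rule=median_rule, sample_quorum=sample_quorum,
    )
    report = FilterReport(
        n_input_sites=matrix.n_sites,
        n_removed_group_filter=len(removed1),
        n_removed_median_filter=len(removed2),
        global_median=rep2.global_median,
        n_retained=after2.n_sites,
    )
    return after2, report


# ---------------------------------------------------------------------------
# TSV interchange

def write_count_matrix_tsv(matrix: CountMatrix, path: str | Path) -> None:
    """First column 'site' as chrom:position:strand, one column per sample."""
    out = matrix.counts.copy()
    out.insert(0, "site", [f"{c}:{p}:{s}" for c, p, s in out.index])
    out.to_csv(path, sep="\t", index=False)


def read_count_matrix_tsv(path: str | Path, samples: Sequence[SampleInfo]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    if "site" not in df.columns:
        raise ValueError(f"{path}: missing 'site' column")
    keys = [tuple(CcggSite.from_key(k)) for k in df["site"]]
    counts = df.drop(columns=["site"])
    counts.index = pd.Index(keys, tupleize_cols=False)
    counts = counts[[s.sample_id for s in samples]]
    counts = counts.sort_index()
    return CountMatrix(counts.astype(np.int64), list(samples))


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path,
                       paths: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttissue\treplicate\tpath\n")
        for s in samples:
            p = (paths or {}).get(s.sample_id, "")
            fh.write(f"{s.sample_id}\t{s.tissue}\t{s.replicate}\t{p}\n")


def read_sample_sheet(path: str | Path) -> tuple[list[SampleInfo], dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    required = {"sample_id", "tissue", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    samples = [
        SampleInfo(r.sample_id, r.tissue, int(r.replicate)) for r in df.itertuples()
    ]
    file_paths = {}
    if "path" in df.columns:
        for r in df.itertuples():
            if isinstance(r.path, str) and r.path:
                file_paths[r.sample_id] = r.path
    return samples, file_paths
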