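"""Reading and writing the package's tabular formats.

Counts are genes x samples TSV (first column = gene identifier); the study
design is a sidecar two-column TSV (sample, group).  Result and benchmark
tables are TSV with a ``#``-prefixed provenance header recording the seed
and permutation settings so runs can be reproduced from the file alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "read_counts",
    "read_groups",
    "write_counts",
    "write_results",
    "write_benchmark",
    "write_truth",
]


@dataclass
class StudyDesign:
    """Two-group sample design: ordered samples and their group labels.

    Group 1 (the first label in file order) is the score numerator / test
    group; group 2 is the reference."""

    samples: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.labels):
            raise ValueError("one label per sample required")
        levels = list(dict.fromkeys(self.labels))
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        self.groups = levels

    def labels_for(self, samples) -> list[str]:
        mapping = dict(zip(self.samples, self.labels))
        missing = [s for s in samples if s not in mapping]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        return [mapping[s] for s in samples]


def read_counts(path, min_mean: float | None = None) -> pd.DataFrame:
    """Read a gene x sample count TSV.

    Rejects duplicate gene identifiers and non-integer cells with the
    offending line number.  ``min_mean`` (e.g. 10) drops genes whose
    average count falls below the floor — the usual low-count filter.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.index.name is None or df.shape[1] == 0:
        raise ValueError(f"{path}: expected a header row and at least one sample column")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        first = dup[0]
        lineno = int(np.where(df.index == first)[0][1]) + 2  # +1 header +1 1-based
        raise ValueError(f"{path}:{lineno}: duplicate gene identifier {first!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count cell ({exc})") from exc
    frac = values.to_numpy() % 1
    if (frac != 0).any():
        gene = values.index[np.where(frac != 0)[0][0]]
        lineno = int(np.where(values.index == gene)[0][0]) + 2
        raise ValueError(f"{path}:{lineno}: non-integer count for gene {gene!r}")
    if (values.to_numpy() < 0).any():
        gene = values.index[np.where((values.to_numpy() < 0).any(axis=1))[0][0]]
        raise ValueError(f"{path}: negative count for gene {gene!r}")
    counts = values.astype(np.int64)
    if min_mean is not None:
        keep = counts.mean(axis=1) >= min_mean
        counts = counts[keep]
    return counts


def read_groups(path) -> StudyDesign:
    """Read the sidecar sample-to-group table (two tab-separated columns,
    no header required; a 'sample<TAB>group' header line is tolerated)."""
    samples, labels = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group'")
            if lineno == 1 and fields == ["sample", "group"]:
                continue
            samples.append(fields[0])
            labels.append(fields[1])
    return StudyDesign(samples, labels)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def write_truth(truth, path_prefix) -> None:
    """Write simulation truth as two TSVs (<prefix>.sets.tsv, .genes.tsv)."""
    truth.set_table.to_csv(f"{path_prefix}.sets.tsv", sep="\t", index=False)
    truth.gene_table.to_csv(f"{path_prefix}.genes.tsv", sep="\t", index=False)


def _provenance_header(result) -> list[str]:
    return [
        "# absgsea results",
        f"# mode={result.mode} statistic={result.statistic}",
        f"# n_perm={result.n_perm} seed={result.seed}",
        f"# fdr={result.fdr} fdr_absolute={result.fdr_absolute}",
        f"# logfc_offset={result.offset}",
    ]


def write_results(result, path) -> None:
    """Write a GseaResults table with a provenance header; reading the file
    back with ``pandas.read_csv(..., sep='\\t', comment='#')`` round-trips
    the values."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in _provenance_header(result):
            fh.write(line + "\n")
        result.results.to_csv(fh, sep="\t", index=False)


def write_benchmark(result, path, seed=None) -> None:
    """Write per-repetition benchmark rows plus the aggregate block."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# absgsea benchmark\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        result.per_repetition.to_csv(fh, sep="\t", index=False)
    agg_path = str(path) + ".aggregate.tsv"
    result.aggregate.to_csv(agg_path, sep="\t", index=False)
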