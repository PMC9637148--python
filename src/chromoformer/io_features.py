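"""Feature pipeline: genomic inputs -> multi-resolution training examples.

Reads gene annotations (BED6 / GTF), per-mark coverage tracks (bedGraph),
promoter-pCRE interaction tables and expression tables, and turns them into
the model's input representation:

* for every gene, log2-transformed binned mean read depths of the histone
  marks over a 40 kbp window centred on the TSS, at 100 / 500 / 2000 bp
  resolution (400 / 80 / 20 bins);
* for up to ``i_max`` interacting pCREs (normalized interaction frequency
  strictly above a threshold, ranked by frequency), the same binned features
  center-aligned and zero-padded to the promoter matrix shape;
* task labels (median-split binary, log2 expression, or log2 fold-change);
* chromosome-disjoint cross-validation folds.

Coordinates are 0-based half-open throughout; GTF is converted on read.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKS",
    "ConfigurationError",
    "InputError",
    "GeneRecord",
    "CoverageTrack",
    "FeatureConfig",
    "SelectedInteractions",
    "TrainingExample",
    "CvFolds",
    "Dataset",
    "bin_signals",
    "build_promoter_features",
    "build_pcre_features",
    "select_interactions",
    "derive_labels",
    "make_cv_folds",
    "read_genes_bed",
    "read_genes_gtf",
    "read_interactions",
    "read_expression",
    "load_coverage_dir",
    "featurize_dataset",
    "save_dataset",
    "load_dataset",
]

#: The seven histone-modification channels used by default. Extra channels
#: (e.g. CTCF) can be appended through FeatureConfig.channels.
MARKS = (
    "H3K4me1",
    "H3K4me3",
    "H3K9me3",
    "H3K27me3",
    "H3K36me3",
    "H3K27ac",
    "H3K9ac",
)


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or incomplete."""


class InputError(ValueError):
    """An input value violates a documented precondition."""


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    expression: float = 0.0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise InputError(f"tss must be >= 0, got {self.tss}")


class CoverageTrack:
    """Per-base read depth for one mark, backed by piecewise-constant intervals.

    Positions outside any covered interval (including positions beyond the
    chromosome end, or chromosomes never seen) read as depth 0.
    """

    def __init__(self, mark_name: str, intervals: Mapping[str, tuple]):
        self.mark_name = mark_name
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise InputError(f"{mark_name}/{chrom}: empty or inverted interval")
            if np.any(starts[1:] < ends[:-1]):
                raise InputError(f"{mark_name}/{chrom}: overlapping intervals")
            # cumulative integral of depth up to the start of each interval
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._chroms[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_bedgraph(cls, path, mark_name: str | None = None) -> "CoverageTrack":
        path = Path(path)
        if mark_name is None:
            mark_name = path.name.split(".")[0]
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            comment="#",
            dtype={"chrom": str},
        )
        intervals = {
            chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
            for chrom, g in df.groupby("chrom", sort=False)
        }
        return cls(mark_name, intervals)

    @classmethod
    def from_dense(cls, mark_name: str, arrays: Mapping[str, np.ndarray]) -> "CoverageTrack":
        """Build from per-chromosome dense per-base arrays (mainly for tests)."""
        intervals = {}
        for chrom, a in arrays.items():
            a = np.asarray(a, dtype=np.float64)
            change = np.flatnonzero(np.diff(a) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(a)]])
            intervals[chrom] = (starts, ends, a[starts])
        return cls(mark_name, intervals)

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of depth over [0, p) for each p (vectorized)."""
        entry = self._chroms.get(chrom)
        if entry is None:
            return np.zeros(len(pos), dtype=np.float64)
        starts, ends, values, cum = entry
        pos = np.asarray(pos, dtype=np.float64)
        j = np.searchsorted(starts, pos, side="right") - 1
        out = np.zeros(len(pos), dtype=np.float64)
        inside = j >= 0
        k = j[inside]
        frac = np.clip(np.minimum(pos[inside], ends[k]) - starts[k], 0.0, None)
        out[inside] = cum[k] + values[k] * frac
        return out

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depths over [start, end); off-track positions are 0."""
        edges = np.arange(start, end + 1, dtype=np.int64)
        return np.diff(self._integral(chrom, edges))

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean depth within consecutive bins delimited by `edges`."""
        F = self._integral(chrom, edges)
        return np.diff(F) / np.diff(edges)


@dataclass(frozen=True)
class FeatureConfig:
    """Featurization settings shared by the pipeline and the model."""

    window: int = 40_000
    resolutions: tuple[int, ...] = (100, 500, 2000)
    pseudocount: float = 1.0
    channels: tuple[str, ...] = MARKS
    threshold: float = 1.5
    i_max: int = 8
    strand_aware: bool = True

    def __post_init__(self):
        for r in self.resolutions:
            if self.window % r != 0:
                raise ConfigurationError(f"window {self.window} not divisible by bin size {r}")
            if (self.window // r) % 2 != 0:
                raise ConfigurationError(f"bin count for resolution {r} must be even")
        if self.i_max < 1:
            raise ConfigurationError("i_max must be >= 1")

    def n_bins(self, resolution: int) -> int:
        return self.window // resolution

    def tss_bin(self, resolution: int) -> int:
        # with an even bin count the TSS sits on a bin edge; the TSS bin is
        # the bin whose left edge is the TSS (0-based index n_r / 2)
        return self.n_bins(resolution) // 2


def bin_signals(
    track: CoverageTrack,
    chrom: str,
    center: int,
    window: int = 40_000,
    bin_size: int = 100,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """log2(mean depth + pseudocount) for non-overlapping bins tiling the window.

    Bins tile ``[center - window/2, center + window/2)`` left to right in
    genomic orientation. Windows running past a chromosome edge read depth 0
    there (documented behaviour, not an error).
    """
    if window % bin_size != 0:
        raise ConfigurationError(f"window {window} not divisible by bin_size {bin_size}")
    left = center - window // 2
    edges = left + bin_size * np.arange(window // bin_size + 1, dtype=np.int64)
    means = track.binned_means(chrom, edges)
    return np.log2(means + pseudocount)


def build_promoter_features(
    gene: GeneRecord,
    tracks: Mapping[str, CoverageTrack],
    config: FeatureConfig,
) -> dict[int, np.ndarray]:
    """Multi-resolution (n_r x C) promoter matrices for a 40 kbp TSS window.

    For minus-strand genes the bin order is reversed (when
    ``config.strand_aware``) so that increasing bin index always means
    downstream of transcription.
    """
    missing = [c for c in config.channels if c not in tracks]
    if missing:
        raise ConfigurationError(f"missing coverage channel(s): {', '.join(missing)}")
    out: dict[int, np.ndarray] = {}
    for r in config.resolutions:
        cols = [
            bin_signals(tracks[c], gene.chrom, gene.tss, config.window, r, config.pseudocount)
            for c in config.channels
        ]
        mat = np.stack(cols, axis=1)
        if config.strand_aware and gene.strand == "-":
            mat = mat[::-1].copy()
        out[r] = mat
    return out


def build_pcre_features(
    interval: tuple[str, int, int],
    tracks: Mapping[str, CoverageTrack],
    resolution: int,
    target_bins: int,
    channels: Sequence[str] = MARKS,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Binned pCRE features, center-aligned and zero-padded to `target_bins` rows.

    The pCRE is covered by its own non-overlapping bins (the last bin may
    extend past the interval end so the bins fully cover it); zero rows are
    appended on both sides to center-align with the promoter matrix. A pCRE
    needing more than `target_bins` bins is center-truncated.
    """
    chrom, start, end = interval
    if end <= start:
        raise InputError(f"degenerate pCRE interval {chrom}:{start}-{end}")
    n = math.ceil((end - start) / resolution)
    if n > target_bins:
        offset = (n - target_bins) // 2
        start = start + offset * resolution
        n = target_bins
    left_pad = (target_bins - n) // 2
    edges = start + resolution * np.arange(n + 1, dtype=np.int64)
    mat = np.zeros((target_bins, len(channels)), dtype=np.float64)
    for ci, c in enumerate(channels):
        means = tracks[c].binned_means(chrom, edges)
        mat[left_pad : left_pad + n, ci] = np.log2(means + pseudocount)
    return mat


@dataclass
class SelectedInteractions:
    """Frequency-filtered, ranked pCREs for one promoter."""

    gene_id: str
    intervals: list[tuple[str, int, int]]
    frequencies: list[float]
    f: np.ndarray  # length i_max, zero-filled beyond the retained pCREs

    def __len__(self) -> int:
        return len(self.intervals)


def select_interactions(
    candidates: Iterable[tuple[tuple[str, int, int], float]],
    threshold: float = 1.5,
    i_max: int = 8,
    gene_id: str = "",
) -> SelectedInteractions:
    """Keep pCREs with normalized frequency strictly above `threshold`,
    ranked by descending frequency (ties by ascending genomic start),
    truncated to at most `i_max`."""
    kept = [(iv, float(fr)) for iv, fr in candidates if float(fr) > threshold]
    kept.sort(key=lambda t: (-t[1], t[0][1], t[0][0], t[0][2]))
    kept = kept[:i_max]
    f = np.zeros(i_max, dtype=np.float64)
    for j, (_, fr) in enumerate(kept):
        f[j] = fr
    return SelectedInteractions(
        gene_id=gene_id,
        intervals=[iv for iv, _ in kept],
        frequencies=[fr for _, fr in kept],
        f=f,
    )


def derive_labels(
    expression: pd.DataFrame,
    task: str,
    cell_type: str | None = None,
    cell_pair: tuple[str, str] | None = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Task labels from an RPKM table (genes x cell types).

    clf  -> 1 iff expression strictly above the within-cell-type median;
    reg  -> log2(RPKM + pseudocount);
    diff -> log2 fold-change between the two cell types in `cell_pair`.
    """
    if task in ("clf", "reg"):
        if cell_type is None:
            if expression.shape[1] != 1:
                raise ConfigurationError("cell_type required when table has several columns")
            cell_type = expression.columns[0]
        x = expression[cell_type].astype(float)
        if (x < 0).any():
            raise InputError("expression values must be non-negative")
        if task == "clf":
            return (x > x.median()).astype(int)
        return np.log2(x + pseudocount)
    if task == "diff":
        if cell_pair is None or len(cell_pair) != 2:
            raise ConfigurationError("task 'diff' requires cell_pair=(cell_a, cell_b)")
        a = expression[cell_pair[0]].astype(float)
        b = expression[cell_pair[1]].astype(float)
        return np.log2((a + pseudocount) / (b + pseudocount))
    raise ConfigurationError(f"unknown task {task!r}")


@dataclass
class CvFolds:
    """Chromosome-disjoint partition of genes into k folds."""

    k: int
    chrom_to_fold: dict[str, int]
    fold_gene_ids: list[list[str]]

    def fold_of(self, chrom: str) -> int:
        return self.chrom_to_fold[chrom]


def make_cv_folds(genes: Sequence[GeneRecord], k: int, seed: int = 0) -> CvFolds:
    """Assign whole chromosomes to folds, greedily balancing gene counts.

    Chromosomes are shuffled with `seed`, then each is assigned to the fold
    currently holding the fewest genes, so no chromosome ever spans folds.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    by_chrom: dict[str, list[str]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.gene_id)
    chroms = sorted(by_chrom)
    if len(chroms) < k:
        raise InputError(f"need at least k={k} chromosomes, got {len(chroms)}")
    rng = np.random.default_rng(seed)
    order = [chroms[i] for i in rng.permutation(len(chroms))]
    sizes = [0] * k
    chrom_to_fold: dict[str, int] = {}
    fold_gene_ids: list[list[str]] = [[] for _ in range(k)]
    for chrom in order:
        fold = int(np.argmin(sizes))
        chrom_to_fold[chrom] = fold
        fold_gene_ids[fold].extend(by_chrom[chrom])
        sizes[fold] += len(by_chrom[chrom])
    return CvFolds(k=k, chrom_to_fold=chrom_to_fold, fold_gene_ids=fold_gene_ids)


# ---------------------------------------------------------------------------
# Readers for the standard input formats
# ---------------------------------------------------------------------------

def read_genes_bed(path) -> list[GeneRecord]:
    """BED6 gene annotation: name column = gene_id; TSS = start (+) / end (-)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    genes = []
    for row in df.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end)
        genes.append(GeneRecord(gene_id=row.name, chrom=row.chrom, tss=tss, strand=row.strand))
    return genes


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_genes_gtf(path, feature: str = "gene") -> list[GeneRecord]:
    """GTF annotation (1-based closed); converted to 0-based half-open on read."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            chrom, start, end, strand, attrs = parts[0], int(parts[3]), int(parts[4]), parts[6], parts[8]
            m = _GTF_GENE_ID.search(attrs)
            if not m:
                continue
            tss = start - 1 if strand == "+" else end
            genes.append(GeneRecord(gene_id=m.group(1), chrom=chrom, tss=tss, strand=strand))
    return genes


def read_interactions(path) -> pd.DataFrame:
    """TSV with header ``gene_id  chrom  start  end  norm_freq``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "norm_freq"}
    if not required.issubset(df.columns):
        raise InputError(f"interaction table must have columns {sorted(required)}")
    return df


def read_expression(path) -> pd.DataFrame:
    """TSV ``gene_id  <cell type columns>`` of RPKM, indexed by gene_id."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def load_coverage_dir(tracks_dir, channels: Sequence[str] = MARKS) -> dict[str, CoverageTrack]:
    """Load ``<mark>.bedGraph`` per channel from a directory."""
    tracks_dir = Path(tracks_dir)
    tracks = {}
    for c in channels:
        path = tracks_dir / f"{c}.bedGraph"
        if not path.exists():
            raise ConfigurationError(f"missing coverage channel(s): {c} ({path} not found)")
        tracks[c] = CoverageTrack.from_bedgraph(path, c)
    return tracks


# ---------------------------------------------------------------------------
# Whole-dataset featurization
# ---------------------------------------------------------------------------

@dataclass
class TrainingExample:
    """All model inputs for one gene, at every configured resolution."""

    gene_id: str
    chrom: str
    promoters: dict[int, np.ndarray]  # resolution -> (n_r, C)
    pcres: dict[int, np.ndarray]  # resolution -> (i_max, n_r, C), zero-padded
    f: np.ndarray  # (i_max,) normalized interaction frequencies
    pad_mask: np.ndarray  # (i_max + 1,) bool, True = real row; [0] is the promoter
    n_interactions: int
    label: float


@dataclass
class Dataset:
    examples: list[TrainingExample]
    folds: CvFolds
    config: FeatureConfig
    task: str

    def __len__(self) -> int:
        return len(self.examples)

    def fold_split(self, fold: int) -> tuple[list[TrainingExample], list[TrainingExample]]:
        """(train, validation) examples for one held-out fold."""
        val_ids = set(self.folds.fold_gene_ids[fold])
        train = [e for e in self.examples if e.gene_id not in val_ids]
        val = [e for e in self.examples if e.gene_id in val_ids]
        return train, val

    def drop_channels(self, channels_to_drop: Sequence[str]) -> "Dataset":
        """Remove histone-mark channels everywhere (HM ablation)."""
        drop = set(channels_to_drop)
        unknown = drop - set(self.config.channels)
        if unknown:
            raise ConfigurationError(f"unknown channel(s): {sorted(unknown)}")
        keep_idx = [i for i, c in enumerate(self.config.channels) if c not in drop]
        if not keep_idx:
            raise ConfigurationError("cannot drop every channel")
        keep = tuple(c for c in self.config.channels if c not in drop)
        if not drop:
            return self
        new_examples = [
            replace(
                e,
                promoters={r: m[:, keep_idx] for r, m in e.promoters.items()},
                pcres={r: m[:, :, keep_idx] for r, m in e.pcres.items()},
            )
            for e in self.examples
        ]
        return Dataset(
            examples=new_examples,
            folds=self.folds,
            config=replace(self.config, channels=keep),
            task=self.task,
        )


def featurize_gene(
    gene: GeneRecord,
    tracks: Mapping[str, CoverageTrack],
    selected: SelectedInteractions,
    config: FeatureConfig,
    label: float,
) -> TrainingExample:
    promoters = build_promoter_features(gene, tracks, config)
    pcres: dict[int, np.ndarray] = {}
    reverse = config.strand_aware and gene.strand == "-"
    for r in config.resolutions:
        n_r = config.n_bins(r)
        block = np.zeros((config.i_max, n_r, len(config.channels)), dtype=np.float64)
        for j, iv in enumerate(selected.intervals):
            mat = build_pcre_features(iv, tracks, r, n_r, config.channels, config.pseudocount)
            if reverse:
                mat = mat[::-1]
            block[j] = mat
        pcres[r] = block
    pad_mask = np.zeros(config.i_max + 1, dtype=bool)
    pad_mask[0] = True
    pad_mask[1 : 1 + len(selected)] = True
    return TrainingExample(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        promoters=promoters,
        pcres=pcres,
        f=selected.f.copy(),
        pad_mask=pad_mask,
        n_interactions=len(selected),
        label=float(label),
    )


def featurize_dataset(
    genes: Sequence[GeneRecord],
    tracks: Mapping[str, CoverageTrack],
    interactions: pd.DataFrame,
    labels: pd.Series,
    config: FeatureConfig = FeatureConfig(),
    k_folds: int = 4,
    seed: int = 0,
    task: str = "clf",
) -> Dataset:
    """Featurize every gene and attach chromosome-disjoint CV folds."""
    genes = [g for g in genes if g.gene_id in labels.index]
    by_gene = dict(tuple(interactions.groupby("gene_id", sort=False))) if len(interactions) else {}
    examples = []
    for g in genes:
        sub = by_gene.get(g.gene_id)
        if sub is None:
            cands = []
        else:
            cands = [
                ((str(r.chrom), int(r.start), int(r.end)), float(r.norm_freq))
                for r in sub.itertuples(index=False)
            ]
        selected = select_interactions(cands, config.threshold, config.i_max, g.gene_id)
        examples.append(featurize_gene(g, tracks, selected, config, labels.loc[g.gene_id]))
    folds = make_cv_folds(genes, k_folds, seed)
    return Dataset(examples=examples, folds=folds, config=config, task=task)


def save_dataset(dataset: Dataset, out_dir) -> Path:
    """Write per-gene tensor files (.npz) plus a manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in dataset.examples:
        path = out_dir / f"{e.gene_id}.npz"
        arrays = {"f": e.f, "pad_mask": e.pad_mask, "label": np.array([e.label])}
        for r in dataset.config.resolutions:
            arrays[f"prom_{r}"] = e.promoters[r]
            arrays[f"pcre_{r}"] = e.pcres[r]
        np.savez(path, **arrays)
        rows.append(
            {
                "gene_id": e.gene_id,
                "chrom": e.chrom,
                "fold": dataset.folds.fold_of(e.chrom),
                "label": e.label,
                "n_interactions": e.n_interactions,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    meta = {
        "window": dataset.config.window,
        "resolutions": list(dataset.config.resolutions),
        "pseudocount": dataset.config.pseudocount,
        "channels": list(dataset.config.channels),
        "threshold": dataset.config.threshold,
        "i_max": dataset.config.i_max,
        "strand_aware": dataset.config.strand_aware,
        "task": dataset.task,
        "k_folds": dataset.folds.k,
        "chrom_to_fold": dataset.folds.chrom_to_fold,
    }
    (out_dir / "dataset.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def load_dataset(in_dir) -> Dataset:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "dataset.json").read_text())
    config = FeatureConfig(
        window=meta["window"],
        resolutions=tuple(meta["resolutions"]),
        pseudocount=meta["pseudocount"],
        channels=tuple(meta["channels"]),
        threshold=meta["threshold"],
        i_max=meta["i_max"],
        strand_aware=meta["strand_aware"],
    )
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t", dtype={"gene_id": str, "chrom": str})
    examples = []
    for row in manifest.itertuples(index=False):
        z = np.load(in_dir / f"{row.gene_id}.npz")
        examples.append(
            TrainingExample(
                gene_id=row.gene_id,
                chrom=row.chrom,
                promoters={r: z[f"prom_{r}"] for r in config.resolutions},
                pcres={r: z[f"pcre_{r}"] for r in config.resolutions},
                f=z["f"],
                pad_mask=z["pad_mask"].astype(bool),
                n_interactions=int(row.n_interactions),
                label=float(row.label),
            )
        )
    fold_gene_ids: list[list[str]] = [[] for _ in range(meta["k_folds"])]
    for row in manifest.itertuples(index=False):
        fold_gene_ids[int(row.fold)].append(row.gene_id)
    folds = CvFolds(
        k=meta["k_folds"],
        chrom_to_fold={str(c): int(f) for c, f in meta["chrom_to_fold"].items()},
        fold_gene_ids=fold_gene_ids,
    )
    return Dataset(examples=examples, folds=folds, config=config, task=meta["task"])


def manifest_checksum(path) -> str:
    """Stable checksum of a text file (used by fixture manifests)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
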