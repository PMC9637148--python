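"""Model interpretation: attention maps and predicted cis-regulatory impact.

PCRI (predicted cis-regulatory impact) quantifies, per gene, how far the
model's regulatory embedding (the promoter embedding after integrating pCRE
interactions) moved away from the bare promoter embedding: both
multi-resolution vectors are standardized component-wise and their Euclidean
distance is taken. Large PCRI means the model attributes a large share of
its prediction to distal cis-regulation. PCRI is computed for validation
genes with each gene's own fold model, z-scored within cell type for
cross-cell-type comparison, and the most variable genes are clustered
(average linkage, correlation distance) to expose differential cis-regulomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .io_features import InputError, TrainingExample
from .model import Chromoformer
from .train import collate

__all__ = [
    "AttentionRecord",
    "extract_attention",
    "compute_pcri",
    "pcri_table",
    "normalize_pcri",
    "rank_variable_genes",
    "cluster_pcri",
    "annotate_pcres",
    "pcre_dose_response",
]


# ---------------------------------------------------------------------------
# Attention extraction
# ---------------------------------------------------------------------------

@dataclass
class AttentionRecord:
    gene_id: str
    module: str  # embedding | pairwise | regulation
    resolution: int
    layer: int
    head: int
    weights: np.ndarray  # (n_q, n_k); rows sum to 1
    pcre_index: int | None = None  # for pairwise maps


def extract_attention(
    model: Chromoformer,
    example: TrainingExample,
    include_pairwise: bool = False,
    include_regulation: bool = False,
) -> list[AttentionRecord]:
    """Attention maps for one gene at inference.

    Always returns the Embedding transformer self-attention maps — one per
    (resolution, head), i.e. six with the default two heads and three
    resolutions. Pairwise cross-attention and Regulation gated-attention maps
    are added on request.
    """
    cfg = model.config
    batch = collate([example], cfg.resolutions)
    out = model(batch, collect_attention=True)
    records: list[AttentionRecord] = []
    for r in cfg.resolutions:
        info = out.bundle["resolutions"][r]
        w_emb = info["attn_emb"][0]  # (heads, n, n)
        for h in range(w_emb.shape[0]):
            records.append(
                AttentionRecord(example.gene_id, "embedding", r, 0, h, w_emb[h].copy())
            )
        if include_pairwise and "attn_pair" in info:
            for layer, w in enumerate(info["attn_pair"]):
                # (B, i_max, heads, n, n) with B = 1
                for j in range(example.n_interactions):
                    for h in range(w.shape[2]):
                        records.append(
                            AttentionRecord(
                                example.gene_id, "pairwise", r, layer, h,
                                w[0, j, h].copy(), pcre_index=j,
                            )
                        )
        if include_regulation and "attn_reg" in info:
            for layer, w in enumerate(info["attn_reg"]):
                for h in range(w.shape[1]):
                    records.append(
                        AttentionRecord(example.gene_id, "regulation", r, layer, h, w[0, h].copy())
                    )
    return records


def attention_tss_profile(model: Chromoformer, example: TrainingExample) -> dict[int, np.ndarray]:
    """Per-resolution (heads x n_bins) attention paid *by* the TSS bin to
    every promoter bin — the profile used to ask which distal regions the
    model consults when embedding the core promoter."""
    cfg = model.config
    records = extract_attention(model, example)
    profiles: dict[int, np.ndarray] = {}
    for r in cfg.resolutions:
        tss = cfg.tss_bin(r)
        rows = [rec.weights[tss] for rec in records if rec.resolution == r]
        profiles[r] = np.stack(rows)
    return profiles


# ---------------------------------------------------------------------------
# PCRI
# ---------------------------------------------------------------------------

def compute_pcri(
    promoter_vector: np.ndarray,
    regulatory_vector: np.ndarray,
    ddof: int = 1,
) -> tuple[float, bool]:
    """Euclidean distance between the standardized multi-resolution promoter
    and regulatory embeddings of one gene.

    Each vector is standardized across its own components (mean 0, sd 1 with
    sample sd by default), which removes per-vector affine shifts introduced
    by the transformation itself. Returns ``(pcri, degenerate)``; a
    zero-variance vector cannot be standardized, so pcri is NaN with the
    degenerate flag set (such genes are excluded from downstream rankings).
    """
    u = np.asarray(promoter_vector, dtype=np.float64)
    v = np.asarray(regulatory_vector, dtype=np.float64)
    if u.shape != v.shape:
        raise InputError("promoter and regulatory vectors must have equal length")
    su, sv = u.std(ddof=ddof), v.std(ddof=ddof)
    if su == 0.0 or sv == 0.0:
        return float("nan"), True
    uz = (u - u.mean()) / su
    vz = (v - v.mean()) / sv
    return float(np.linalg.norm(uz - vz)), False


def pcri_table(oof_predictions: pd.DataFrame, cell_type: str = "cell") -> pd.DataFrame:
    """PCRI per gene from a cross-validation prediction table carrying
    ``promoter_vector`` / ``regulatory_vector`` columns (each gene is scored
    by its own fold's model). Degenerate genes are dropped with a warning."""
    rows = []
    n_degenerate = 0
    for rec in oof_predictions.itertuples(index=False):
        pcri, degenerate = compute_pcri(rec.promoter_vector, rec.regulatory_vector)
        if degenerate:
            n_degenerate += 1
            continue
        rows.append({"gene_id": rec.gene_id, "cell_type": cell_type, "pcri": pcri})
    if n_degenerate:
        warnings.warn(f"excluded {n_degenerate} gene(s) with zero-variance embeddings")
    return pd.DataFrame(rows)


def normalize_pcri(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score PCRI within each cell type (population sd, so per-cell-type
    mean 0 / sd 1 holds exactly and the operation is idempotent)."""
    table = table.copy()

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        if sd == 0.0:
            warnings.warn("constant PCRI within a cell type: normalized values set to 0")
            return x * 0.0
        return (x - x.mean()) / sd

    table["normalized_pcri"] = table.groupby("cell_type")["pcri"].transform(_z)
    return table


def rank_variable_genes(table: pd.DataFrame, top_n: int = 1000) -> list[str]:
    """Genes ranked by the variance of normalized PCRI across cell types
    (descending); genes missing in some cell type are excluded with a warning."""
    wide = table.pivot(index="gene_id", columns="cell_type", values="normalized_pcri")
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(f"excluded {len(wide) - len(complete)} gene(s) missing in some cell type")
    var = complete.var(axis=1, ddof=1).sort_values(ascending=False, kind="stable")
    return var.index[:top_n].tolist()


def cluster_pcri(matrix: pd.DataFrame) -> dict:
    """Average-linkage hierarchical clustering of genes and of cell types on
    distance = 1 - Pearson correlation. Zero-variance rows/columns (undefined
    correlation) are excluded with a warning."""
    keep_rows = matrix.index[matrix.std(axis=1, ddof=0) > 0]
    keep_cols = matrix.columns[matrix.std(axis=0, ddof=0) > 0]
    if len(keep_rows) < len(matrix.index) or len(keep_cols) < len(matrix.columns):
        warnings.warn("excluded zero-variance rows/columns from clustering")
    m = matrix.loc[keep_rows, keep_cols].to_numpy(dtype=np.float64)
    return {
        "gene_linkage": linkage(m, method="average", metric="correlation"),
        "cell_linkage": linkage(m.T, method="average", metric="correlation"),
        "genes": list(keep_rows),
        "cell_types": list(keep_cols),
    }


# ---------------------------------------------------------------------------
# pCRE annotation overlap and dose-response
# ---------------------------------------------------------------------------

def annotate_pcres(pcres: pd.DataFrame, annotation_bed: pd.DataFrame) -> pd.DataFrame:
    """Flag each pCRE (gene_id, chrom, start, end) that overlaps any interval
    of a BED-like annotation table (chrom, start, end); half-open coordinates."""
    out = pcres.copy()
    flags = np.zeros(len(out), dtype=bool)
    for chrom, ann in annotation_bed.groupby("chrom"):
        sel = out["chrom"] == chrom
        if not sel.any():
            continue
        a = ann.sort_values("start")
        starts = a["start"].to_numpy()
        run_max_end = np.maximum.accumulate(a["end"].to_numpy())
        idx = np.searchsorted(starts, out.loc[sel, "end"].to_numpy(), side="left")
        has = idx > 0
        hit = np.zeros(sel.sum(), dtype=bool)
        hit[has] = run_max_end[idx[has] - 1] > out.loc[sel, "start"].to_numpy()[has]
        flags[sel.to_numpy()] = hit
    out["annotated"] = flags
    return out


def pcre_dose_response(
    predictions: pd.DataFrame,
    annotations: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Relate per-gene PCRI to the number of annotated pCREs.

    ``predictions`` carries gene_id, pcri and (optionally) expression;
    ``annotations`` is a per-pCRE table with gene_id and a boolean
    ``annotated`` column (e.g. from :func:`annotate_pcres`). Genes absent
    from the annotation table count zero annotated pCREs. Returns a summary
    with median PCRI (and expression) per pCRE-count bin, plus the gene-level
    Spearman rank correlation between count and PCRI.
    """
    if len(annotations):
        counts = (
            annotations[annotations["annotated"].astype(bool)]
            .groupby("gene_id")
            .size()
            .rename("n_annotated")
        )
    else:
        counts = pd.Series(dtype=int, name="n_annotated")
    df = predictions.copy()
    df["n_annotated"] = df["gene_id"].map(counts).fillna(0).astype(int)
    if df.empty:
        return pd.DataFrame(columns=["n_annotated", "n_genes", "median_pcri"]), float("nan")
    agg = {"n_genes": ("gene_id", "size"), "median_pcri": ("pcri", "median")}
    if "expression" in df.columns:
        agg["median_expression"] = ("expression", "median")
    summary = df.groupby("n_annotated").agg(**agg).reset_index()
    if df["n_annotated"].nunique() > 1:
        rho = float(stats.spearmanr(df["n_annotated"], df["pcri"]).statistic)
    else:
        rho = float("nan")
    return summary, rho
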