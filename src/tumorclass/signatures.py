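"""Exhaustion gene-signature set algebra.

Workflow: threshold each differential-expression contrast (FDR ≤ 0.01,
|log2FC| ≥ 2) into up/down gene sets, intersect the in vitro and in vivo
exhausted-vs-activated contrasts direction-wise into the *experimental
signature*, map mouse symbols to human orthologs, intersect with a human
exhausted-cluster gene list into the *exhausted signature*, and finally
filter for transcription factors. Every step is pure set algebra with full
provenance of what was dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SignatureSet",
    "filter_significant",
    "intersect_signatures",
    "map_to_human",
    "build_exhausted_signature",
    "filter_transcription_factors",
    "normalize_mouse_symbol",
    "normalize_human_symbol",
    "read_ortholog_map",
    "write_signature",
    "read_signature",
]


def normalize_mouse_symbol(symbol: str) -> str:
    """Mouse convention: Title-case (Pdcd1, Bhlhe40)."""
    s = str(symbol).strip()
    return s[:1].upper() + s[1:].lower() if s else s


def normalize_human_symbol(symbol: str) -> str:
    """Human convention: upper-case (PDCD1, BHLHE40)."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class SignatureSet:
    """Direction-split gene signature; up and down are always disjoint."""

    up: frozenset[str]
    down: frozenset[str]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"genes in both directions: {sorted(overlap)[:5]}...")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    def all_genes(self) -> frozenset[str]:
        return self.up | self.down

    def with_note(self, note: str) -> "SignatureSet":
        return SignatureSet(self.up, self.down, self.provenance + (note,))


def filter_significant(
    table: pd.DataFrame,
    fdr_max: float = 0.01,
    lfc_min: float = 2.0,
    *,
    gene_col: str = "gene",
    lfc_col: str = "log2FoldChange",
    fdr_col: str = "padj",
    contrast_name: str | None = None,
) -> SignatureSet:
    """Threshold a DE table into up/down significant gene sets.

    Both thresholds are inclusive: a gene is significant when
    ``fdr ≤ fdr_max`` and ``|log2FC| ≥ lfc_min``; the sign of the fold
    change gives the direction.
    """
    missing = {gene_col, lfc_col, fdr_col} - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing column(s) {sorted(missing)}")
    genes = table[gene_col].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"duplicate gene symbol in DE table: {dup!r}")
    lfc = pd.to_numeric(table[lfc_col])
    fdr = pd.to_numeric(table[fdr_col])
    if ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("adjusted p-values outside [0, 1]")
    sig = fdr <= fdr_max
    up = frozenset(genes[sig & (lfc >= lfc_min)])
    down = frozenset(genes[sig & (lfc <= -lfc_min)])
    name = contrast_name or "contrast"
    return SignatureSet(
        up, down,
        (f"filter_significant({name}, fdr<={fdr_max}, |lfc|>={lfc_min}): "
         f"{len(up)} up, {len(down)} down",))


def intersect_signatures(a: SignatureSet, b: SignatureSet) -> SignatureSet:
    """Direction-concordant intersection of two signatures.

    Genes significant in both inputs but in opposite directions are
    excluded and counted in provenance.
    """
    up = a.up & b.up
    down = a.down & b.down
    discordant = (a.up & b.down) | (a.down & b.up)
    return SignatureSet(
        frozenset(up), frozenset(down),
        a.provenance + b.provenance + (
            f"intersect: {len(up)} up, {len(down)} down, "
            f"{len(discordant)} direction-discordant excluded",))


def read_ortholog_map(path, *, mouse_col: str = "mouse_symbol",
                      human_col: str = "human_symbol") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {mouse_col, human_col} - set(df.columns)
    if missing:
        raise ValueError(f"ortholog map missing column(s) {sorted(missing)}")
    return df.rename(columns={mouse_col: "mouse_symbol",
                              human_col: "human_symbol"})


def map_to_human(
    sig: SignatureSet,
    ortholog_map: pd.DataFrame,
    *,
    mouse_col: str = "mouse_symbol",
    human_col: str = "human_symbol",
) -> SignatureSet:
    """Translate a mouse signature to human symbols via an ortholog map.

    One-to-many orthologs expand (every mapped human symbol is kept);
    unmapped mouse genes are dropped and counted; a human symbol that
    would land in both directions is removed as conflicting. Symbols are
    case-normalised (mouse Title-case, human upper-case) before joining.
    """
    if ortholog_map.empty:
        raise ValueError("empty ortholog map")
    pairs = ortholog_map[[mouse_col, human_col]].dropna()
    mapping: dict[str, set[str]] = {}
    for m, h in pairs.itertuples(index=False):
        mapping.setdefault(normalize_mouse_symbol(m), set()).add(
            normalize_human_symbol(h))

    def translate(genes: frozenset[str]) -> tuple[set[str], int]:
        out: set[str] = set()
        unmapped = 0
        for g in genes:
            targets = mapping.get(normalize_mouse_symbol(g))
            if targets:
                out |= targets
            else:
                unmapped += 1
        return out, unmapped

    up, up_unmapped = translate(sig.up)
    down, down_unmapped = translate(sig.down)
    conflicting = up & down
    up -= conflicting
    down -= conflicting
    return SignatureSet(
        frozenset(up), frozenset(down),
        sig.provenance + (
            f"map_to_human: {len(up)} up, {len(down)} down; "
            f"{up_unmapped + down_unmapped} unmapped dropped; "
            f"{len(conflicting)} direction-conflicting human symbols removed",))


def build_exhausted_signature(
    experimental: SignatureSet,
    human_exhausted_genes: Iterable[str],
    *,
    human_up: Iterable[str] | None = None,
    human_down: Iterable[str] | None = None,
) -> SignatureSet:
    """Intersect the human-mapped experimental signature with the human
    exhausted-cluster gene list.

    By default the human list is direction-agnostic (one set restricting
    both directions); pass ``human_up``/``human_down`` to require
    direction concordance on the human side too.
    """
    if human_up is not None or human_down is not None:
        up_ref = frozenset(normalize_human_symbol(g) for g in (human_up or ()))
        down_ref = frozenset(normalize_human_symbol(g) for g in (human_down or ()))
        mode = "direction-concordant"
    else:
        ref = frozenset(normalize_human_symbol(g) for g in human_exhausted_genes)
        if not ref:
            raise ValueError("empty human exhausted gene list")
        up_ref = down_ref = ref
        mode = "direction-agnostic"
    up = experimental.up & up_ref
    down = experimental.down & down_ref
    return SignatureSet(
        frozenset(up), frozenset(down),
        experimental.provenance + (
            f"exhausted signature ({mode}): {len(up)} up, {len(down)} down, "
            f"{len(up) + len(down)} total",))


def filter_transcription_factors(sig: SignatureSet,
                                 tf_list: Iterable[str]) -> SignatureSet:
    """Restrict each direction to annotated transcription factors."""
    tfs = frozenset(normalize_human_symbol(g) for g in tf_list)
    if not tfs:
        raise ValueError("empty transcription-factor list")
    up = sig.up & tfs
    down = sig.down & tfs
    return SignatureSet(
        frozenset(up), frozenset(down),
        sig.provenance + (f"TF filter: {len(up)} up, {len(down)} down",))


def write_signature(sig: SignatureSet, path) -> None:
    """Two-column TSV (gene, direction), sorted for reproducibility."""
    rows = ([(g, "up") for g in sorted(sig.up)]
            + [(g, "down") for g in sorted(sig.down)])
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
        path, sep="\t", index=False)


def read_signature(path) -> SignatureSet:
    df = pd.read_csv(path, sep="\t")
    up = frozenset(df.loc[df["direction"] == "up", "gene"].astype(str))
    down = frozenset(df.loc[df["direction"] == "down", "gene"].astype(str))
    return SignatureSet(up, down, (f"read from {path}",))
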