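"""Candidate merging, gap filling, and K-locus panel assembly.

Candidates come from three sources — sweep regions, QTL-interval
overlaps, and GWAS hits — and are deduplicated with source priority
gwas > qtl > sweep > gapfill (trait-linked content is kept
preferentially). Gaps larger than the target spacing are filled greedily
from the filtered resequencing pool; when the union exceeds K, loci are
dropped from the densest neighbourhoods first, lowest-priority sources
first, so spacing uniformity is preserved. All intervals are 0-based
half-open (BED convention); locus positions are 1-based (VCF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_PRIORITY = {"gwas": 0, "qtl": 1, "sweep": 2, "gapfill": 3}

#: Probe length used for designability screening (bp).
PROBE_LENGTH = 120


# ----------------------------------------------------------------- overlaps

def _check_sorted_intervals(df: pd.DataFrame, what: str) -> None:
    grp = df.groupby("chrom", sort=False)["start"] if "start" in df else df.groupby(
        "chrom", sort=False
    )["pos"]
    for chrom, s in grp:
        if not s.is_monotonic_increasing:
            raise ValueError(f"{what} not sorted within chromosome {chrom!r}")


def overlap_qtl(candidates: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Loci falling inside >= 1 QTL region, tagged with all matching traits.

    ``candidates`` needs columns ``chrom, pos`` (1-based); ``regions``
    needs ``chrom, start, end`` 0-based half-open and ``trait_tag``. Both
    must be position-sorted within chromosome; the search is a linear
    sort-merge sweep with an active-region set.
    """
    if regions.empty:
        return candidates.iloc[0:0].assign(trait_tags="")
    _check_sorted_intervals(candidates, "candidate loci")
    _check_sorted_intervals(regions, "QTL regions")
    out_idx: list[int] = []
    out_tags: list[str] = []
    for chrom, cand in candidates.groupby("chrom", sort=False):
        reg = regions[regions["chrom"] == chrom]
        if reg.empty:
            continue
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        tags = reg["trait_tag"].to_numpy()
        pos0 = cand["pos"].to_numpy() - 1  # to 0-based
        r = 0
        active: list[int] = []  # indices of regions whose start has passed
        for i, p in enumerate(pos0):
            while r < len(starts) and starts[r] <= p:
                active.append(r)
                r += 1
            active = [j for j in active if ends[j] > p]
            if active:
                out_idx.append(cand.index[i])
                out_tags.append(",".join(sorted(set(tags[j] for j in active))))
    result = candidates.loc[out_idx].copy()
    result["trait_tags"] = out_tags
    return result


# ---------------------------------------------------------------- gap filling

def _chrom_gaps(positions: np.ndarray, chrom_len: int) -> np.ndarray:
    """Adjacent-gap lengths including the two chromosome-end flanks."""
    edges = np.concatenate(([0], positions - 1, [chrom_len]))
    return np.diff(edges)


def fill_gaps(
    selected: pd.DataFrame,
    pool: pd.DataFrame,
    target_spacing: int,
    min_maf: float = 0.05,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Greedy uniform-density gap filling.

    Wherever adjacent selected loci (or chromosome ends) are more than
    ``target_spacing`` apart, the pool locus with maf >= ``min_maf``
    closest to each ideal equally-spaced position is inserted. Prior
    selections are never removed; unfillable gaps are logged and
    reported in the result's ``attrs["unfilled_gaps"]``.

    Returns the added loci (columns of ``pool`` plus ``source="gapfill"``).
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    pool_ok = pool if "maf" not in pool.columns else pool[pool["maf"] >= min_maf]
    unfilled = []
    added_rows = []
    chroms = list(
        dict.fromkeys(list(selected["chrom"]) + list(pool_ok["chrom"]))
    )
    if not len(pool_ok) and len(selected):
        logger.warning("gap filling: empty pool; gaps cannot be filled")
    for chrom in chroms:
        sel_pos = np.sort(selected.loc[selected["chrom"] == chrom, "pos"].to_numpy())
        cpool = pool_ok[pool_ok["chrom"] == chrom]
        ppos = cpool["pos"].to_numpy()
        order = np.argsort(ppos)
        ppos = ppos[order]
        cpool = cpool.iloc[order]
        if chrom_lengths and chrom in chrom_lengths:
            chrom_len = chrom_lengths[chrom]
        else:
            hi = [v.max() for v in (sel_pos, ppos) if len(v)]
            chrom_len = int(max(hi)) if hi else 0
        taken = set(sel_pos)
        bounds = np.concatenate(([0], sel_pos - 1, [chrom_len]))
        for left, right in zip(bounds[:-1], bounds[1:]):
            gap = right - left
            if gap <= target_spacing:
                continue
            k = int(np.ceil(gap / target_spacing)) - 1  # ideal insertions
            ideal = left + (np.arange(1, k + 1) * gap) / (k + 1)
            filled_any = False
            for t in ideal:
                lo = np.searchsorted(ppos, left + 1, side="left")
                hi_i = np.searchsorted(ppos, right + 1, side="left")
                if lo >= hi_i:
                    break
                cand_pos = ppos[lo:hi_i]
                j = lo + int(np.argmin(np.abs(cand_pos - (t + 1))))
                p = int(ppos[j])
                if p in taken:
                    continue
                taken.add(p)
                added_rows.append(cpool.iloc[j])
                filled_any = True
            if not filled_any:
                unfilled.append({"chrom": chrom, "start": int(left), "end": int(right)})
    if unfilled:
        logger.warning("gap filling: %d gaps had no eligible pool locus", len(unfilled))
    added = (
        pd.DataFrame(added_rows).drop_duplicates(subset=["chrom", "pos"])
        if added_rows
        else pool.iloc[0:0].copy()
    )
    if len(added):
        added = added.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        added["source"] = "gapfill"
    added.attrs["unfilled_gaps"] = pd.DataFrame(unfilled)
    return added


# ------------------------------------------------------------------ assembly

@dataclass
class PanelSpec:
    """The assembled panel: ordered loci with source labels."""

    loci: pd.DataFrame  # chrom, pos, ref, alt, source, trait_tags
    target_size: int
    chrom_lengths: dict | None = field(default=None)

    @property
    def size(self) -> int:
        return len(self.loci)


def _dedup_union(parts: list[tuple[pd.DataFrame, str]]) -> pd.DataFrame:
    frames = []
    for df, source in parts:
        if df is None or df.empty:
            continue
        d = df[[c for c in ("chrom", "pos", "ref", "alt", "trait_tags") if c in df.columns]].copy()
        if "source" in df.columns:
            d["source"] = df["source"]
        else:
            d["source"] = source
        frames.append(d)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "source", "trait_tags"])
    union = pd.concat(frames, ignore_index=True)
    union["prio"] = union["source"].map(SOURCE_PRIORITY)
    union = union.sort_values(
        ["chrom", "pos", "prio"], kind="mergesort"
    ).drop_duplicates(subset=["chrom", "pos"], keep="first")
    return union.drop(columns="prio").reset_index(drop=True)


def _max_gap_per_chrom(df: pd.DataFrame, chrom_lengths: dict | None) -> dict:
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        ln = (chrom_lengths or {}).get(chrom, int(grp["pos"].max()))
        out[chrom] = int(_chrom_gaps(np.sort(grp["pos"].to_numpy()), ln).max())
    return out


def assemble_panel(
    sweep_loci: pd.DataFrame,
    qtl_loci: pd.DataFrame,
    gwas_loci: pd.DataFrame,
    pool: pd.DataFrame,
    k: int = 54_188,
    target_spacing: int = 50_000,
    min_maf: float = 0.05,
    chrom_lengths: dict | None = None,
) -> PanelSpec:
    """Assemble the final K-locus panel.

    Source lists are deduplicated (priority gwas > qtl > sweep); if the
    union is smaller than K it is gap-filled from the pool — first to
    the target spacing, then by splitting the currently largest gaps
    until exactly K loci; if larger than K, gapfill loci in the densest
    neighbourhoods go first, then sweep, then qtl. Deterministic: ties
    break by genomic order.
    """
    if k <= 0:
        raise ValueError("panel size K must be positive")
    union = _dedup_union([(gwas_loci, "gwas"), (qtl_loci, "qtl"), (sweep_loci, "sweep")])
    pool = pool.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    avail = len(
        pd.concat([union[["chrom", "pos"]], pool[["chrom", "pos"]]]).drop_duplicates()
    )
    if k > avail:
        raise ValueError(
            f"K={k} exceeds the {avail} distinct loci available in candidates + pool"
        )

    panel = union
    if len(panel) < k:
        added = fill_gaps(panel, pool, target_spacing, min_maf, chrom_lengths)
        panel = _dedup_union([(panel, "keep"), (added, "gapfill")])
        if len(panel) > k:
            panel = _drop_to_k(panel, k, chrom_lengths, protect_non_gapfill=True)
        elif len(panel) < k:
            panel = _grow_to_k(panel, pool, k, min_maf, chrom_lengths)
    elif len(panel) > k:
        panel = _drop_to_k(panel, k, chrom_lengths, protect_non_gapfill=False)
    panel = panel.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if "trait_tags" not in panel.columns:
        panel["trait_tags"] = ""
    panel["trait_tags"] = panel["trait_tags"].fillna("")
    return PanelSpec(loci=panel, target_size=k, chrom_lengths=chrom_lengths)


def _neighbour_space(df: pd.DataFrame, chrom_lengths: dict | None) -> np.ndarray:
    """Per-locus sum of flanking gaps (small = dense neighbourhood)."""
    space = np.empty(len(df))
    pos = df["pos"].to_numpy()
    chroms = df["chrom"].to_numpy()
    i = 0
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        p = pos[sel]
        ln = (chrom_lengths or {}).get(chrom, int(p.max()))
        edges = np.concatenate(([0], p - 1, [ln]))
        gaps = np.diff(edges)
        space[i : i + len(p)] = gaps[:-1] + gaps[1:]
        i += len(p)
    return space


def _drop_to_k(panel, k, chrom_lengths, protect_non_gapfill):
    panel = panel.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    n_drop = len(panel) - k
    prio = panel["source"].map(SOURCE_PRIORITY).to_numpy()
    space = _neighbour_space(panel, chrom_lengths)
    # drop order: gapfill first (densest first), then sweep, then qtl, then gwas
    order = np.lexsort((panel["pos"].to_numpy(), space, -prio))
    if protect_non_gapfill:
        order = order[panel["source"].to_numpy()[order] == "gapfill"]
        if len(order) < n_drop:
            rest = np.lexsort((panel["pos"].to_numpy(), space, -prio))
            rest = rest[panel["source"].to_numpy()[rest] != "gapfill"]
            order = np.concatenate([order, rest])
    drop = set(order[:n_drop].tolist())
    return panel.loc[[i for i in range(len(panel)) if i not in drop]].reset_index(drop=True)


def _grow_to_k(panel, pool, k, min_maf, chrom_lengths):
    """Split the largest current gaps with pool loci until exactly K."""
    pool_ok = pool if "maf" not in pool.columns else pool[pool["maf"] >= min_maf]
    have = set(zip(panel["chrom"], panel["pos"]))
    extra = pool_ok[~pool_ok.apply(lambda r: (r["chrom"], r["pos"]) in have, axis=1)]
    if len(panel) + len(extra) < k:
        raise ValueError("pool too small to reach the requested panel size")
    import heapq

    by_chrom = {c: g["pos"].to_numpy() for c, g in extra.groupby("chrom")}
    used: dict[str, np.ndarray] = {
        c: np.zeros(len(p), dtype=bool) for c, p in by_chrom.items()
    }
    heap = []
    for chrom, grp in panel.groupby("chrom", sort=False):
        p = np.sort(grp["pos"].to_numpy())
        ln = (chrom_lengths or {}).get(chrom, int(p.max()))
        edges = np.concatenate(([0], p - 1, [ln]))
        for left, right in zip(edges[:-1], edges[1:]):
            heapq.heappush(heap, (-(right - left), chrom, int(left), int(right)))
    rows = []
    while len(panel) + len(rows) < k and heap:
        neg_gap, chrom, left, right = heapq.heappop(heap)
        ppos = by_chrom.get(chrom)
        if ppos is None:
            continue
        mid = (left + right) / 2
        lo = np.searchsorted(ppos, left + 1, side="left")
        hi = np.searchsorted(ppos, right + 1, side="left")
        cand = [j for j in range(lo, hi) if not used[chrom][j]]
        if not cand:
            continue
        j = min(cand, key=lambda j: abs(ppos[j] - mid))
        used[chrom][j] = True
        row = extra[(extra["chrom"] == chrom) & (extra["pos"] == ppos[j])].iloc[0]
        rows.append(row)
        p = int(ppos[j])
        heapq.heappush(heap, (-(p - 1 - left), chrom, left, p - 1))
        heapq.heappush(heap, (-(right - (p - 1)), chrom, p - 1, right))
    if len(panel) + len(rows) < k:
        raise ValueError("pool exhausted before reaching the requested panel size")
    added = pd.DataFrame(rows)
    added["source"] = "gapfill"
    return _dedup_union([(panel, "keep"), (added, "gapfill")])


# ------------------------------------------------------------- designability

def designability_filter(
    loci: pd.DataFrame,
    pool: pd.DataFrame,
    fasta=None,
    probe_length: int = PROBE_LENGTH,
    gc_range: tuple = (0.3, 0.7),
) -> pd.DataFrame:
    """Transparent proxy for probe designability.

    Keeps loci with no *other* pool variant inside the probe window
    (probe_length bp centred on the locus) and, when a reference FASTA
    is supplied, probe-window GC content within ``gc_range``. The GC
    check needs sequence and is skipped without a FASTA.
    """
    half = probe_length // 2
    keep = []
    pool_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in pool.groupby("chrom")}
    fa = None
    if fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta))
    for _, row in loci.iterrows():
        ppos = pool_by_chrom.get(row["chrom"], np.array([], dtype=int))
        lo = np.searchsorted(ppos, row["pos"] - half, side="left")
        hi = np.searchsorted(ppos, row["pos"] + half, side="right")
        n_in_window = hi - lo - int(lo < hi and row["pos"] in ppos[lo:hi])
        ok = n_in_window == 0
        if ok and fa is not None:
            seq = str(fa[row["chrom"]][max(row["pos"] - 1 - half, 0) : row["pos"] - 1 + half]).upper()
            gc = (seq.count("G") + seq.count("C")) / max(len(seq), 1)
            ok = gc_range[0] <= gc <= gc_range[1]
        keep.append(ok)
    return loci.loc[np.asarray(keep, dtype=bool)].reset_index(drop=True)


# ------------------------------------------------------------------- reports

def density_report(panel: PanelSpec, bins=None) -> dict:
    """Adjacent-gap histogram, fraction of gaps <= 100 kb, per-chromosome
    counts, and per-chromosome maximum gap."""
    if panel.size == 0:
        raise ValueError("empty panel")
    gaps = []
    per_chrom = {}
    for chrom, grp in panel.loci.groupby("chrom", sort=False):
        p = np.sort(grp["pos"].to_numpy())
        per_chrom[chrom] = len(p)
        gaps.extend(np.diff(p).tolist())  # gaps between adjacent panel loci only
    gaps = np.asarray(gaps, dtype=float)
    if bins is None:
        bins = np.linspace(0, max(gaps.max() if len(gaps) else 1, 1), 21)
    hist, edges = np.histogram(gaps, bins=bins)
    return {
        "gaps": gaps,
        "hist": hist,
        "bin_edges": edges,
        "frac_le_100kb": float((gaps <= 100_000).mean()) if len(gaps) else float("nan"),
        "per_chrom_counts": per_chrom,
        "max_gap_per_chrom": _max_gap_per_chrom(panel.loci, panel.chrom_lengths),
    }
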