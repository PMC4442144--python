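"""Decoding: merge mates, parse merged reads into ligamer chains, count.

The decoder anchors on the pool structure rather than free alignment: a
merged read is parsed left to right as a chain of ligamer segments, each
verified against the catalog with a bounded per-segment mismatch count, and
constrained by the pool's adjacency relation.  Cross-pool continuations are
allowed during parsing, which is exactly what exposes template switching in
a dual-barcoded design: a parse mixing pool-1 and pool-2 barcodes is the
switch signature.  A read whose chain parses only when one segment's barcode
and flanking arms disagree (barcode of variant Y, arms of sibling X) is
classed near-cognate.  Reads are tried in the given orientation first, then
reverse complemented; assignment requires a unique consistent isoform.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .design import INTERNAL, TERMINAL_3P, TERMINAL_5P, LigamerPool
from .errors import DecodeError
from .model import GeneModel, VariantRegion
from .thermo import reverse_complement

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"
NEAR_COGNATE = "near_cognate"
SWITCHED = "switched"
STATUSES = (ASSIGNED, AMBIGUOUS, UNASSIGNED, NEAR_COGNATE, SWITCHED)


@dataclass(frozen=True)
class MergedRead:
    """One merged mate pair: length = len(r1) + len(r2) - overlap_len.

    ``uncertain`` holds merged-coordinate positions where the mates
    disagreed inside the overlap: exactly one mate erred there, so
    downstream matching treats them as low-confidence.
    """

    sequence: str
    overlap_len: int
    n_overlap_mismatches: int
    uncertain: tuple[int, ...] = ()


def merge_pairs(
    r1: str,
    r2: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Merge a mate pair via their overlapping 3' ends.

    r2 is reverse complemented and slid against r1; among overlap lengths
    with mismatch fraction <= ``max_mismatch_frac`` the one maximizing the
    number of matching bases wins (ties to the longer overlap).  Overlap
    bases are resolved in favor of r1.  Returns ``None`` when no overlap of
    at least ``min_overlap`` qualifies.
    """
    if not r1 or not r2:
        raise DecodeError("empty mate sequence")
    b = reverse_complement(r2)
    max_o = min(len(r1), len(b))
    best: tuple[int, int, int] | None = None  # (matches, overlap, mismatches)
    tail = r1[-max_o:] if max_o == len(b) else None
    for o in range(max_o, min_overlap - 1, -1):
        if r1[len(r1) - o :] == b[:o]:  # exact fast path (C-speed compare)
            best_exact = (o, o, 0)
            if best is None or best_exact[:2] > best[:2]:
                best = best_exact
            break
        mm = sum(x != y for x, y in zip(r1[len(r1) - o :], b[:o]))
        if mm / o <= max_mismatch_frac:
            cand = (o - mm, o, mm)
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None:
        return None
    matches, o, mm = best
    start = len(r1) - o
    uncertain = tuple(
        start + i for i, (x, y) in enumerate(zip(r1[start:], b[:o])) if x != y
    )
    return MergedRead(
        sequence=r1 + b[o:],
        overlap_len=o,
        n_overlap_mismatches=mm,
        uncertain=uncertain,
    )


@dataclass(frozen=True)
class Assignment:
    """Outcome of decoding one read.

    ``pools_observed`` lists the pool labels of the informative (recoded)
    barcodes seen along the parse; two labels at once is the
    template-switch signature.
    """

    read_id: str
    status: str
    isoform_key: str = ""
    segment_mismatches: tuple[int, ...] = ()
    pools_observed: tuple[str, ...] = ()
    reason: str = ""


@dataclass(frozen=True)
class _Entry:
    pool_label: str
    lig_id: str
    sequence: str
    kind: str
    informative: bool
    variant_id: str | None  # variant id when the ligamer targets one
    hybrid_of: str | None = None  # barcode-donor variant for hybrid entries


class Decoder:
    """Parses merged reads against one or two differentially coded pools."""

    def __init__(
        self,
        model: GeneModel,
        pools: LigamerPool | tuple[LigamerPool, ...],
        max_mismatch_per_segment: int = 2,
        max_parses: int = 16,
    ):
        self.model = model
        self.pools = tuple(pools) if isinstance(pools, (tuple, list)) else (pools,)
        if not self.pools or not self.pools[0].ligamers:
            raise DecodeError("decoder needs at least one non-empty pool")
        self.max_mm = max_mismatch_per_segment
        self.max_parses = max_parses
        self.dual = len(self.pools) > 1

        variant_ids = {
            v.id for r in model.variant_regions for v in r.variants if not v.is_skip
        }
        self._vregion_ids = [r.id for r in model.variant_regions]
        self._region_of_variant = {
            v.id: r.id for r in model.variant_regions for v in r.variants
        }
        self._skip_of_region = {
            r.id: next((v.id for v in r.variants if v.is_skip), None)
            for r in model.variant_regions
        }

        # which ligamer ids carry pool-specific (informative) barcodes
        codes: dict[str, set[str]] = {}
        for pool in self.pools:
            for lig in pool.ligamers:
                if lig.kind == INTERNAL:
                    codes.setdefault(lig.id, set()).add(lig.spacer)
        informative = {lid for lid, cs in codes.items() if len(cs) > 1}

        self._entries: dict[tuple[str, str], _Entry] = {}
        self._starts: list[_Entry] = []
        self._succ: dict[tuple[str, str], list[_Entry]] = {}
        adj_ids: dict[str, list[str]] = {}
        for pool in self.pools:
            for a, b_ in pool.adjacency:
                adj_ids.setdefault(a, [])
                if b_ not in adj_ids[a]:
                    adj_ids[a].append(b_)
        for pool in self.pools:
            for lig in pool.ligamers:
                e = _Entry(
                    pool_label=pool.pool_label,
                    lig_id=lig.id,
                    sequence=lig.sequence,
                    kind=lig.kind,
                    informative=lig.id in informative,
                    variant_id=lig.id if lig.id in variant_ids else None,
                )
                self._entries[(pool.pool_label, lig.id)] = e
                if lig.kind == TERMINAL_5P:
                    self._starts.append(e)
        for (plabel, lid), _e in self._entries.items():
            succs: list[_Entry] = []
            for nxt in adj_ids.get(lid, []):
                for pool in self.pools:  # cross-pool continuation allowed
                    key = (pool.pool_label, nxt)
                    if key in self._entries:
                        succs.append(self._entries[key])
            self._succ[(plabel, lid)] = succs

        # hybrid entries (arms of X, barcode of Y) for near-cognate detection
        self._hybrids: dict[tuple[str, str], list[_Entry]] = {}
        for pool in self.pools:
            by_id = pool.by_id
            for region in model.variant_regions:
                vids = [v.id for v in region.variants if not v.is_skip and v.id in by_id]
                for x in vids:
                    lx = by_id[x]
                    hybs = []
                    for y in vids:
                        if y == x:
                            continue
                        ly = by_id[y]
                        hybs.append(
                            _Entry(
                                pool_label=pool.pool_label,
                                lig_id=x,
                                sequence=lx.arm_up + ly.spacer + lx.arm_down,
                                kind=INTERNAL,
                                informative=lx.id in informative,
                                variant_id=x,
                                hybrid_of=y,
                            )
                        )
                    self._hybrids[(pool.pool_label, x)] = hybs

    # -- segment matching --------------------------------------------------

    def _seg_mm(self, read: str, pos: int, seq: str, mask: frozenset[int]) -> int | None:
        """Mismatch count of ``seq`` at ``pos``, ignoring masked positions
        (overlap disagreements: known single-mate errors)."""
        end = pos + len(seq)
        if end > len(read):
            return None
        seg = read[pos:end]
        if seg == seq:
            return 0
        if mask:
            mm = sum(
                a != b and (pos + i) not in mask
                for i, (a, b) in enumerate(zip(seg, seq))
            )
        else:
            mm = sum(a != b for a, b in zip(seg, seq))
        return mm if mm <= self.max_mm else None

    # -- parsing -----------------------------------------------------------

    def _parses(
        self, read: str, allow_hybrids: bool, mask: frozenset[int]
    ) -> list[list[tuple[_Entry, int]]]:
        out: list[list[tuple[_Entry, int]]] = []

        def step(pos: int, entry: _Entry, path: list[tuple[_Entry, int]]) -> None:
            if len(out) >= self.max_parses:
                return
            if entry.kind == TERMINAL_3P:
                if pos == len(read):
                    out.append(path.copy())
                return
            for nxt in self._succ[(entry.pool_label, entry.lig_id)]:
                candidates = [nxt]
                if allow_hybrids and nxt.variant_id is not None:
                    candidates += self._hybrids.get((nxt.pool_label, nxt.lig_id), [])
                for cand in candidates:
                    mm = self._seg_mm(read, pos, cand.sequence, mask)
                    if mm is None:
                        continue
                    path.append((cand, mm))
                    step(pos + len(cand.sequence), cand, path)
                    path.pop()

        for start in self._starts:
            mm = self._seg_mm(read, 0, start.sequence, mask)
            if mm is not None:
                step(len(start.sequence), start, [(start, mm)])
        return out

    def _summarize(self, read_id: str, parses: list) -> Assignment | None:
        results = set()
        details = []
        for path in parses:
            entries = [e for e, _mm in path]
            mms = tuple(mm for _e, mm in path)
            labels = tuple(sorted({e.pool_label for e in entries if e.informative}))
            has_hybrid = any(e.hybrid_of is not None for e in entries)
            key = self._implied_key(entries)
            if key is None:
                continue
            results.add((key, labels, has_hybrid))
            details.append((key, labels, has_hybrid, mms))
        if not details:
            return None
        if len(results) > 1:
            return Assignment(read_id, AMBIGUOUS, reason="multiple consistent chains")
        key, labels, has_hybrid, mms = details[0]
        if len(labels) > 1:
            return Assignment(
                read_id, SWITCHED, segment_mismatches=mms, pools_observed=labels
            )
        if has_hybrid:
            return Assignment(
                read_id,
                NEAR_COGNATE,
                segment_mismatches=mms,
                pools_observed=labels,
                reason="barcode inconsistent with flanking arms",
            )
        return Assignment(
            read_id, ASSIGNED, isoform_key=key, segment_mismatches=mms, pools_observed=labels
        )

    def _implied_key(self, entries: list[_Entry]) -> str | None:
        chosen: dict[str, str] = {}
        for e in entries:
            if e.variant_id is not None:
                rid = self._region_of_variant[e.variant_id]
                if rid in chosen and chosen[rid] != e.variant_id:
                    return None
                chosen[rid] = e.variant_id
        parts = []
        for rid in self._vregion_ids:
            if rid in chosen:
                parts.append(chosen[rid])
            elif self._skip_of_region[rid] is not None:
                parts.append(self._skip_of_region[rid])
            else:
                return None  # region unaccounted for
        return "|".join(parts)

    def assign(self, merged: str | MergedRead, read_id: str = "") -> Assignment:
        if isinstance(merged, MergedRead):
            read = merged.sequence
            fwd_mask = frozenset(merged.uncertain)
        else:
            read = merged
            fwd_mask = frozenset()
        n = len(read)
        rev_mask = frozenset(n - 1 - p for p in fwd_mask)
        for oriented, mask in ((read, fwd_mask), (reverse_complement(read), rev_mask)):
            parses = self._parses(oriented, allow_hybrids=False, mask=mask)
            res = self._summarize(read_id, parses)
            if res is not None:
                return res
            parses = self._parses(oriented, allow_hybrids=True, mask=mask)
            res = self._summarize(read_id, parses)
            if res is not None:
                return res
        return Assignment(read_id, UNASSIGNED, reason="no chain decomposition")


def assign_read(
    merged: str | MergedRead,
    model: GeneModel,
    pools: LigamerPool | tuple[LigamerPool, ...],
    max_mismatch_per_segment: int = 2,
    read_id: str = "",
) -> Assignment:
    """One-shot wrapper around :class:`Decoder` for a single merged read."""
    return Decoder(model, pools, max_mismatch_per_segment).assign(merged, read_id)


# ---------------------------------------------------------------------------
# counting and reports
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Isoform read counts for one sample plus per-status tallies.

    Conservation: the status totals sum to the number of input read pairs;
    ``counts`` covers only status ``assigned``.
    """

    sample: str
    counts: dict[str, int] = field(default_factory=dict)
    status_totals: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.status_totals.values())

    @property
    def assigned_total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"isoform_key": list(self.counts), "count": list(self.counts.values()),
             "sample": self.sample}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample: str | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        sample = sample or (str(df["sample"].iloc[0]) if "sample" in df and len(df) else "")
        counts = dict(zip(df["isoform_key"].astype(str), df["count"].astype(int)))
        return cls(sample=sample, counts=counts,
                   status_totals={ASSIGNED: int(df["count"].sum())})


def count_isoforms(assignments: list[Assignment], sample_label: str = "sample") -> CountTable:
    """Tally assigned reads per isoform; all other statuses counted aside."""
    counts: Counter[str] = Counter()
    statuses: Counter[str] = Counter()
    for a in assignments:
        statuses[a.status] += 1
        if a.status == ASSIGNED:
            counts[a.isoform_key] += 1
    return CountTable(
        sample=sample_label, counts=dict(counts), status_totals=dict(statuses)
    )


@dataclass(frozen=True)
class SwitchReport:
    """Template-switch summary for a dual-pool run."""

    applicable: bool
    n_switched: int
    n_total: int
    fraction: float
    patterns: tuple[tuple[str, ...], ...]


def switch_report(assignments: list[Assignment], dual_pool: bool = True) -> SwitchReport:
    """Counts and fraction of switched reads plus the cross-pool patterns seen."""
    n_total = len(assignments)
    if not dual_pool:
        return SwitchReport(False, 0, n_total, 0.0, ())
    switched = [a for a in assignments if a.status == SWITCHED]
    patterns = tuple(sorted({a.pools_observed for a in switched}))
    frac = len(switched) / n_total if n_total else 0.0
    return SwitchReport(True, len(switched), n_total, frac, patterns)


def barcode_map(pools: LigamerPool | tuple[LigamerPool, ...]) -> pd.DataFrame:
    """Barcode -> (ligamer id, pool label) table (TSV-ready)."""
    pools = tuple(pools) if isinstance(pools, (tuple, list)) else (pools,)
    rows = [
        {"barcode": lig.spacer, "ligamer_id": lig.id, "pool_label": p.pool_label}
        for p in pools
        for lig in p.ligamers
        if lig.kind == INTERNAL
    ]
    return pd.DataFrame(rows)


def decode_pairs(
    reads,
    model: GeneModel,
    pools: LigamerPool | tuple[LigamerPool, ...],
    sample_label: str = "sample",
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    max_mismatch_per_segment: int = 2,
) -> tuple[CountTable, list[Assignment]]:
    """Full pipeline: merge each mate pair, assign, and tally.

    Pairs that fail to merge are counted ``unassigned`` (the loss is
    explicit, not silent).
    """
    decoder = Decoder(model, pools, max_mismatch_per_segment)
    assignments: list[Assignment] = []
    for r in reads:
        merged = merge_pairs(r.r1, r.r2, min_overlap, max_mismatch_frac)
        if merged is None:
            assignments.append(Assignment(r.read_id, UNASSIGNED, reason="merge_failed"))
            continue
        assignments.append(decoder.assign(merged, read_id=r.read_id))
    return count_isoforms(assignments, sample_label), assignments
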