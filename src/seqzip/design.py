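"""Ligamer pool design: terminal/internal splint oligos, barcodes, screening.

A ligamer is a 40–60 nt DNA oligo with one (terminal) or two (internal)
regions of complementarity to the target RNA.  Internal ligamers hybridize to
the beginning and end of their target piece, looping out the sequence in
between, and carry a barcode in the spacer between the two arms.  Terminal
ligamers anchor the profiled span and carry amplification primer tails.

Arm lengths are chosen by Tm: terminal arms are trimmed from the far end
until Tm <= ``tm_max`` (65 °C); internal arms are trimmed from the inside of
the target outward until each arm falls in ``arm_tm_target ±
arm_tm_tolerance`` (60 ± 5 °C) while the whole oligo stays within
``max_len`` (60 nt).

Orientation convention: arm strings are stored transcript-sense, i.e. an arm
equals its hybridization footprint on the isoform sequence; the physical
oligo is the reverse complement (Tm and ΔG are identical either way).
Coordinates are 0-based half-open, local to the region/variant piece named
in ``target_coords``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import DesignConfig
from .errors import (
    CapacityError,
    DesignError,
    InfeasibleDesignError,
    SearchExhaustedError,
)
from .model import ConstitutiveBlock, GeneModel, VariantRegion
from .thermo import duplex_free_energy, melting_temp, reverse_complement

TERMINAL_5P = "terminal_5p"
TERMINAL_3P = "terminal_3p"
INTERNAL = "internal"


@dataclass(frozen=True)
class Ligamer:
    """One splint oligo.

    ``arm_up`` anneals to the 5'-ward footprint, ``arm_down`` to the 3'-ward
    one (empty for terminals, whose single arm sits in ``arm_up``).  The
    ``spacer`` holds the barcode (internal) or the primer tail (terminal).
    ``target_coords`` lists (piece_id, start, end) footprints, piece-local,
    0-based half-open.  Every ligamer that is not 5'-most in a chain needs a
    5' phosphate for ligation.
    """

    id: str
    kind: str
    arm_up: str
    arm_down: str
    spacer: str
    target_coords: tuple[tuple[str, int, int], ...]
    has_5p_phosphate: bool
    flags: tuple[str, ...] = ()

    @property
    def sequence(self) -> str:
        """Assembled oligo, transcript-sense, 5'->3' along the product."""
        if self.kind == TERMINAL_5P:
            return self.spacer + self.arm_up
        if self.kind == TERMINAL_3P:
            return self.arm_up + self.spacer
        return self.arm_up + self.spacer + self.arm_down

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(a for a in (self.arm_up, self.arm_down) if a)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BarcodeSet:
    """Barcodes with a pairwise Hamming-distance guarantee.

    Equal-length codes are pairwise at Hamming distance >= ``min_hamming``;
    no code contains a homopolymer run longer than 3; all codes are unique.
    """

    codes: tuple[str, ...]
    length: int
    min_hamming: int
    seed: int


@dataclass(frozen=True)
class LigamerPool:
    """All ligamers for one gene plus the valid-successor relation.

    ``adjacency`` holds directed (ligamer_id, ligamer_id) pairs whose
    hybridization footprints abut on at least one isoform; chains in the
    product index must follow it.  ``pool_label`` distinguishes the
    differentially barcoded copies in a dual-pool (template-switch control)
    design.
    """

    gene_id: str
    ligamers: tuple[Ligamer, ...]
    adjacency: tuple[tuple[str, str], ...]
    pool_label: str = "pool1"

    def __post_init__(self) -> None:
        ids = [l.id for l in self.ligamers]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate ligamer ids in pool")

    def __len__(self) -> int:
        return len(self.ligamers)

    def get(self, lig_id: str) -> Ligamer:
        for l in self.ligamers:
            if l.id == lig_id:
                return l
        raise KeyError(lig_id)

    @property
    def by_id(self) -> dict[str, Ligamer]:
        return {l.id: l for l in self.ligamers}

    def successors(self, lig_id: str) -> tuple[str, ...]:
        return tuple(b for a, b in self.adjacency if a == lig_id)


# ---------------------------------------------------------------------------
# arm trimming
# ---------------------------------------------------------------------------


def _terminal_arm(region_seq: str, anchor: str, config: DesignConfig) -> tuple[str, tuple[str, ...]]:
    """Longest anchored arm with Tm <= tm_max, trimming from the far end.

    ``anchor="3p"`` keeps the region's 3' end fixed (arm is a suffix, for the
    5'-terminal ligamer which must abut the next region); ``anchor="5p"``
    keeps the 5' end fixed (arm is a prefix).  Deterministic: lengths are
    scanned from full length downward and the first length whose Tm drops to
    tm_max or below wins.
    """
    n = len(region_seq)
    flags: list[str] = []
    arm = None
    for length in range(n, 1, -1):
        cand = region_seq[n - length :] if anchor == "3p" else region_seq[:length]
        if melting_temp(cand, config.duplex) <= config.tm_max:
            arm = cand
            if length == n:
                flags.append("exhausted")
            break
    if arm is None:  # even the 2-mer exceeds tm_max; cannot happen with real params
        raise DesignError("no arm length with Tm <= tm_max")
    if melting_temp(arm, config.duplex) < config.tm_floor:
        flags.append("low_tm")
    return arm, tuple(flags)


def design_terminal_ligamer(
    region_seq: str,
    region_id: str,
    end: str,
    primer_tail: str,
    config: DesignConfig = DesignConfig(),
    lig_id: str | None = None,
) -> Ligamer:
    """Design the terminal ligamer anchoring one end of the profiled span.

    ``end="five_prime"``: the arm is the longest suffix of the region whose
    Tm does not exceed ``tm_max`` (one more nucleotide, when available,
    pushes Tm above it); the primer tail is prepended.  ``end="three_prime"``
    mirrors this with a prefix arm and an appended tail.  A region whose full
    complement already melts below ``tm_max`` yields a full-length arm with
    an ``"exhausted"`` flag; a very weak arm additionally gets ``"low_tm"``.
    """
    if not region_seq:
        raise DesignError(f"terminal region {region_id!r} is empty")
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be 'five_prime' or 'three_prime'")
    anchor = "3p" if end == "five_prime" else "5p"
    arm, flags = _terminal_arm(region_seq.upper().replace("U", "T"), anchor, config)
    n = len(region_seq)
    if end == "five_prime":
        coords = (region_id, n - len(arm), n)
        kind = TERMINAL_5P
    else:
        coords = (region_id, 0, len(arm))
        kind = TERMINAL_3P
    return Ligamer(
        id=lig_id or f"{region_id}.{'t5' if kind == TERMINAL_5P else 't3'}",
        kind=kind,
        arm_up=arm,
        arm_down="",
        spacer=primer_tail,
        target_coords=(coords,),
        has_5p_phosphate=(kind == TERMINAL_3P),
        flags=flags,
    )


def _window_lengths(seq: str, anchor: str, config: DesignConfig) -> list[int]:
    """Arm lengths (anchored prefix/suffix) whose Tm falls in the window."""
    low, high = config.arm_tm_window
    out = []
    for length in range(config.min_arm_length, len(seq) + 1):
        cand = seq[:length] if anchor == "5p" else seq[len(seq) - length :]
        if low <= melting_temp(cand, config.duplex) <= high:
            out.append(length)
    return out


def design_internal_ligamer(
    upstream_target: tuple[str, str, int],
    downstream_target: tuple[str, str, int],
    barcode: str,
    config: DesignConfig = DesignConfig(),
    lig_id: str | None = None,
) -> Ligamer:
    """Design an internal ligamer spanning (and looping out) a target piece.

    Each target is ``(sequence, piece_id, offset)``: the upstream arm is a
    prefix of ``upstream_target`` (anchored at the piece boundary it must
    abut), the downstream arm a suffix of ``downstream_target``; both are
    trimmed from the inside outward.  Constraints: each arm Tm within
    ``arm_tm_target ± arm_tm_tolerance`` and total length (arms + barcode)
    <= ``max_len``.  Among feasible (len_up, len_down) pairs the tie-break
    is lexicographic: longest upstream arm first, then longest downstream
    arm.  Raises :class:`InfeasibleDesignError` naming the violated
    constraint when no pair qualifies.
    """
    up_seq, up_id, up_off = upstream_target
    down_seq, down_id, down_off = downstream_target
    up_seq = up_seq.upper().replace("U", "T")
    down_seq = down_seq.upper().replace("U", "T")
    up_ok = _window_lengths(up_seq, "5p", config)
    down_ok = _window_lengths(down_seq, "3p", config)
    if not up_ok or not down_ok:
        which = "upstream" if not up_ok else "downstream"
        raise InfeasibleDesignError(
            f"no {which} arm length reaches Tm window {config.arm_tm_window}", "arm_tm"
        )
    budget = config.max_len - len(barcode)
    pairs = [(u, d) for u in up_ok for d in down_ok if u + d <= budget]
    if not pairs:
        raise InfeasibleDesignError(
            f"no arm pair fits arms + {len(barcode)} nt barcode <= {config.max_len} nt",
            "max_len",
        )
    l_up, l_down = max(pairs)  # lexicographic: upstream first
    return Ligamer(
        id=lig_id or up_id,
        kind=INTERNAL,
        arm_up=up_seq[:l_up],
        arm_down=down_seq[len(down_seq) - l_down :],
        spacer=barcode,
        target_coords=(
            (up_id, up_off, up_off + l_up),
            (down_id, down_off + len(down_seq) - l_down, down_off + len(down_seq)),
        ),
        has_5p_phosphate=True,
    )


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _max_homopolymer(code: str) -> int:
    best = run = 1
    for a, b in zip(code, code[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_barcodes(
    n: int,
    length: int,
    min_hamming: int = 3,
    seed: int = 0,
    attempt_budget: int = 200_000,
) -> BarcodeSet:
    """Random-search ``n`` barcodes of ``length`` nt, pairwise Hamming >=
    ``min_hamming``, no homopolymer run > 3.  Reproducible under ``seed``.
    """
    if n > 4**length:
        raise CapacityError(f"{n} codes requested but only {4**length} exist at length {length}")
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    attempts = 0
    while len(codes) < n:
        if attempts >= attempt_budget:
            raise SearchExhaustedError(
                f"gave up after {attempt_budget} draws with {len(codes)}/{n} codes "
                f"(length={length}, min_hamming={min_hamming})"
            )
        attempts += 1
        code = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if _max_homopolymer(code) > 3:
            continue
        if any(_hamming(code, c) < min_hamming for c in codes):
            continue
        codes.append(code)
    return BarcodeSet(codes=tuple(codes), length=length, min_hamming=min_hamming, seed=seed)


# ---------------------------------------------------------------------------
# pool planning
# ---------------------------------------------------------------------------


def _internal_specs(model: GeneModel) -> list[dict]:
    """Per-internal-ligamer design inputs, in transcript order.

    One spec per separating constitutive block and per non-skip variant.
    Targets are the two halves of the piece, so the ligamer anneals to the
    piece's beginning and end and loops out its middle.
    """
    specs: list[dict] = []
    for region in model.regions[1:-1]:
        if isinstance(region, ConstitutiveBlock):
            seq = region.sequence
            half = len(seq) // 2
            specs.append(
                {
                    "lig_id": region.id,
                    "piece_id": region.id,
                    "up": (seq[:half], region.id, 0),
                    "down": (seq[half:], region.id, half),
                    "region_id": region.id,
                    "variant_id": None,
                }
            )
        else:
            for v in region.variants:
                if v.is_skip:
                    continue
                seq = v.sequence or ""
                half = len(seq) // 2
                specs.append(
                    {
                        "lig_id": v.id,
                        "piece_id": v.id,
                        "up": (seq[:half], v.id, 0),
                        "down": (seq[half:], v.id, half),
                        "region_id": region.id,
                        "variant_id": v.id,
                    }
                )
    return specs


def _structural_adjacency(model: GeneModel, t5_id: str, t3_id: str) -> tuple[tuple[str, str], ...]:
    """Valid-successor pairs implied by region order, skip outcomes included."""
    edges: set[tuple[str, str]] = set()
    frontier = [t5_id]
    for region in model.regions[1:-1]:
        if isinstance(region, ConstitutiveBlock):
            options = [region.id]
            passthrough = False
        else:
            options = [v.id for v in region.variants if not v.is_skip]
            passthrough = any(v.is_skip for v in region.variants)
        for prev in frontier:
            for opt in options:
                edges.add((prev, opt))
        frontier = options + (frontier if passthrough else [])
    for prev in frontier:
        edges.add((prev, t3_id))
    return tuple(sorted(edges))


def plan_pool(
    model: GeneModel,
    config: DesignConfig = DesignConfig(),
    pool_label: str = "pool1",
    barcode_seed: int = 0,
    barcodes: BarcodeSet | None = None,
    barcode_lengths: dict[str, int] | None = None,
) -> LigamerPool:
    """Plan the complete ligamer pool for a gene model.

    The pool contains exactly one terminal ligamer at each end of the
    profiled span, one internal ligamer per non-skip variant (skip outcomes
    add none — the flanking ligamers simply become adjacent), and one
    internal ligamer per constitutive block separating variant regions, so
    ``len(pool) = 2 + n_variant_exons + n_separating_blocks``.  Internal
    barcodes are drawn deterministically from ``barcode_seed`` (or supplied
    via ``barcodes``); ``barcode_lengths`` overrides the barcode width for
    individual ligamer ids (product-length tuning).  Design is fully
    deterministic: identical inputs give byte-identical pools.
    """
    first, last = model.regions[0], model.regions[-1]
    if not isinstance(first, ConstitutiveBlock) or not isinstance(last, ConstitutiveBlock):
        raise DesignError(
            "profiled span must start and end with a constitutive block to anchor terminals"
        )
    specs = _internal_specs(model)
    overrides = barcode_lengths or {}
    if barcodes is None:
        default_ids = [s["lig_id"] for s in specs if s["lig_id"] not in overrides]
        pool_codes: dict[str, str] = {}
        if default_ids:
            bset = generate_barcodes(
                len(default_ids), config.barcode_length, config.min_hamming, seed=barcode_seed
            )
            pool_codes.update(dict(zip(default_ids, bset.codes)))
        for i, (lig_id, blen) in enumerate(sorted(overrides.items())):
            bset = generate_barcodes(1, blen, config.min_hamming, seed=barcode_seed + 1000 + i)
            pool_codes[lig_id] = bset.codes[0]
    else:
        if len(barcodes.codes) < len(specs):
            raise DesignError(f"{len(specs)} barcodes needed, {len(barcodes.codes)} supplied")
        pool_codes = {s["lig_id"]: c for s, c in zip(specs, barcodes.codes)}

    t5 = design_terminal_ligamer(
        first.sequence, first.id, "five_prime", config.primer_tail_fwd, config
    )
    t3 = design_terminal_ligamer(
        last.sequence, last.id, "three_prime", config.primer_tail_rev, config
    )
    internals = [
        design_internal_ligamer(
            s["up"], s["down"], pool_codes[s["lig_id"]], config, lig_id=s["lig_id"]
        )
        for s in specs
    ]
    adjacency = _structural_adjacency(model, t5.id, t3.id)
    return LigamerPool(
        gene_id=model.gene_id,
        ligamers=(t5, *internals, t3),
        adjacency=adjacency,
        pool_label=pool_label,
    )


def plan_dual_pools(
    model: GeneModel,
    config: DesignConfig = DesignConfig(),
    barcode_seed: int = 0,
    recode: str | list[str] = "all",
) -> tuple[LigamerPool, LigamerPool]:
    """Two copies of the pool differing only in (some) internal barcodes.

    Splitting a sample across two such pools turns template switching into a
    detectable signature: a chimeric product carries barcodes from both
    pools.  ``recode="all"`` (default) gives every internal ligamer a
    pool-specific code; a list of ligamer ids recodes only those (the others
    share codes and are uninformative for switching).  Codes are drawn as one
    Hamming-separated set, so pool-1 and pool-2 codes also keep their
    distance from each other.
    """
    specs = _internal_specs(model)
    ids = [s["lig_id"] for s in specs]
    recode_ids = set(ids) if recode == "all" else set(recode)
    unknown = recode_ids - set(ids)
    if unknown:
        raise DesignError(f"recode ids not in pool: {sorted(unknown)}")
    n = len(ids)
    bset = generate_barcodes(
        n + len(recode_ids), config.barcode_length, config.min_hamming, seed=barcode_seed
    )
    codes1 = dict(zip(ids, bset.codes[:n]))
    extra = iter(bset.codes[n:])
    codes2 = {i: (next(extra) if i in recode_ids else codes1[i]) for i in ids}

    def _with_codes(codes: dict[str, str], label: str) -> LigamerPool:
        pool = plan_pool(
            model,
            config,
            pool_label=label,
            barcodes=BarcodeSet(
                codes=tuple(codes[i] for i in ids),
                length=config.barcode_length,
                min_hamming=config.min_hamming,
                seed=barcode_seed,
            ),
        )
        return pool

    return _with_codes(codes1, "pool1"), _with_codes(codes2, "pool2")


def validate_pool(pool: LigamerPool, config: DesignConfig = DesignConfig()) -> None:
    """Assert pool invariants; raises :class:`DesignError` on violation.

    Checks: one terminal of each kind; internal length <= max_len with both
    arm Tms inside the window; terminal arm Tm <= tm_max; unique barcodes;
    5'-phosphate present on every non-5'-terminal ligamer.
    """
    kinds = [l.kind for l in pool.ligamers]
    if kinds.count(TERMINAL_5P) != 1 or kinds.count(TERMINAL_3P) != 1:
        raise DesignError("pool must contain exactly one terminal ligamer per end")
    low, high = config.arm_tm_window
    seen_codes: dict[str, str] = {}
    for l in pool.ligamers:
        if l.kind == INTERNAL:
            if len(l) > config.max_len:
                raise DesignError(f"{l.id}: length {len(l)} > max_len {config.max_len}")
            for arm in l.arms:
                tm = melting_temp(arm, config.duplex)
                if not (low <= tm <= high):
                    raise DesignError(f"{l.id}: arm Tm {tm:.2f} outside [{low}, {high}]")
            if l.spacer in seen_codes:
                raise DesignError(f"barcode {l.spacer} shared by {seen_codes[l.spacer]} and {l.id}")
            seen_codes[l.spacer] = l.id
            if not l.has_5p_phosphate:
                raise DesignError(f"{l.id}: internal ligamer lacks 5' phosphate")
        else:
            tm = melting_temp(l.arm_up, config.duplex)
            if tm > config.tm_max and "exhausted" not in l.flags:
                raise DesignError(f"{l.id}: terminal arm Tm {tm:.2f} > tm_max")
            if l.kind == TERMINAL_3P and not l.has_5p_phosphate:
                raise DesignError(f"{l.id}: 3' terminal lacks 5' phosphate")


# ---------------------------------------------------------------------------
# specificity / energy-gap screen
# ---------------------------------------------------------------------------


def _arm_hits(arm: str, transcript: str, max_mismatch: int = 1) -> list[tuple[int, int]]:
    """(position, n_mismatches) of every <=max_mismatch occurrence of arm."""
    n, m = len(transcript), len(arm)
    if m == 0 or m > n:
        return []
    t = np.frombuffer(transcript.encode(), dtype=np.uint8)
    a = np.frombuffer(arm.encode(), dtype=np.uint8)
    # mismatch counts for every offset via shifted comparisons
    counts = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        counts += t[j : j + n - m + 1] != a[j]
    return [(int(i), int(c)) for i, c in enumerate(counts) if c <= max_mismatch]


def _variant_cluster_map(model: GeneModel) -> dict[str, tuple[str, tuple[str, ...]]]:
    """variant id -> (region id, all variant ids in that region)."""
    out: dict[str, tuple[str, tuple[str, ...]]] = {}
    for region in model.variant_regions:
        ids = tuple(v.id for v in region.variants if not v.is_skip)
        for vid in ids:
            out[vid] = (region.id, ids)
    return out


def _variant_seq(model: GeneModel, vid: str) -> str:
    for region in model.variant_regions:
        for v in region.variants:
            if v.id == vid:
                return v.sequence or ""
    raise KeyError(vid)


def ligamer_target_dg(
    lig: Ligamer, piece_seq: str, config: DesignConfig = DesignConfig()
) -> float:
    """Summed arm ΔG of an internal ligamer against a candidate piece.

    Arms are compared at their anchored positions (prefix/suffix of the
    piece); the physical oligo arm is the reverse complement of the stored
    transcript-sense arm.
    """
    total = 0.0
    for arm, (pid, start, end) in zip((lig.arm_up, lig.arm_down), lig.target_coords):
        if not arm:
            continue
        if start == 0:  # anchored at piece 5' end
            segment = piece_seq[: len(arm)]
        else:  # anchored at piece 3' end
            segment = piece_seq[len(piece_seq) - len(arm) :]
        if len(segment) < len(arm):
            segment = segment.ljust(len(arm), "N").replace("N", "A")  # degenerate pad
        total += duplex_free_energy(reverse_complement(arm), segment, config.duplex)
    return total


def screen_pool_specificity(
    pool: LigamerPool,
    model: GeneModel,
    transcripts: dict[str, str] | None = None,
    config: DesignConfig = DesignConfig(),
):
    """Off-target and cognate/near-cognate energy-gap report for a pool.

    Every arm is searched as an exact and 1-mismatch substring against the
    transcript set (default: a covering set of isoform sequences, one per
    variant); hits outside the arm's own footprint count as off-target.  For
    each variant-targeting ligamer, ΔG against its cognate variant and
    against every other variant in its cluster is computed; ``gap`` is the
    nearest near-cognate ΔG minus the cognate ΔG, flagged when below
    ``dg_gap_min``.  Returns a pandas DataFrame, one row per ligamer.
    """
    import pandas as pd

    if transcripts is None:
        transcripts = covering_transcripts(model)
    cluster_of = _variant_cluster_map(model)
    # precompute piece layouts per transcript for cognate-position lookup
    layouts = {}
    for name, _seq in transcripts.items():
        try:
            layouts[name] = model.isoform_layout(name)
        except Exception:
            layouts[name] = {}

    rows = []
    for lig in pool.ligamers:
        off_hits = 0
        for tname, tseq in transcripts.items():
            layout = layouts.get(tname, {})
            for arm, (pid, start, end) in zip((lig.arm_up, lig.arm_down), lig.target_coords):
                if not arm:
                    continue
                cognate_pos = layout[pid] + start if pid in layout else None
                for pos, _mm in _arm_hits(arm, tseq, max_mismatch=1):
                    if pos != cognate_pos:
                        off_hits += 1
        cognate_dg = np.nan
        nearest_dg = np.nan
        nearest_id = ""
        gap = np.nan
        flagged = False
        vid = lig.id if lig.id in cluster_of else None
        if vid is not None:
            _region, siblings = cluster_of[vid]
            cognate_dg = ligamer_target_dg(lig, _variant_seq(model, vid), config)
            near = [
                (ligamer_target_dg(lig, _variant_seq(model, w), config), w)
                for w in siblings
                if w != vid
            ]
            if near:
                nearest_dg, nearest_id = min(near)
                gap = nearest_dg - cognate_dg
                flagged = gap < config.dg_gap_min
        rows.append(
            {
                "ligamer_id": lig.id,
                "kind": lig.kind,
                "off_target_hits": off_hits,
                "cognate_dg": cognate_dg,
                "nearest_near_cognate_dg": nearest_dg,
                "nearest_near_cognate_id": nearest_id,
                "gap": gap,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def covering_transcripts(model: GeneModel) -> dict[str, str]:
    """A small isoform set in which every non-skip variant appears at least once."""
    vregions = model.variant_regions
    if not vregions:
        return {"": model.isoform_sequence("")}
    pools = [[v.id for v in r.variants if not v.is_skip] or [v.id for v in r.variants] for r in vregions]
    depth = max(len(p) for p in pools)
    out: dict[str, str] = {}
    for i in range(depth):
        key = "|".join(p[min(i, len(p) - 1)] for p in pools)
        if key not in out:
            out[key] = model.isoform_sequence(key)
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def pool_to_tsv(pool: LigamerPool, path: str | Path | None = None) -> str:
    """Order-sheet TSV: id, transcript-sense sequence, synthesis sequence
    (reverse complement), 5'-phosphate flag, kind, pool label."""
    lines = ["id\tsequence\tsynthesis_sequence\tphos_5p\tkind\tpool"]
    for l in pool.ligamers:
        lines.append(
            f"{l.id}\t{l.sequence}\t{reverse_complement(l.sequence)}\t"
            f"{int(l.has_5p_phosphate)}\t{l.kind}\t{pool.pool_label}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def pool_to_fasta(pool: LigamerPool, path: str | Path | None = None) -> str:
    lines = []
    for l in pool.ligamers:
        lines.append(f">{pool.gene_id}|{pool.pool_label}|{l.id}")
        lines.append(l.sequence)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
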