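"""Synthetic data: gene models, isoform mixtures, ligation artifacts, reads.

Emulates the assay's control experiments at desk scale: gene models with a
tunable degree of inter-variant sequence similarity, defined isoform
mixtures (e.g. 100:10:1), ligation with configurable template-switch and
near-cognate rates across dual barcoded pools, and 250 nt paired-end reads
whose 3' ends overlap.  Every simulated product is logged in a truth ledger
so decoders can be validated read-by-read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import INTERNAL, Ligamer, LigamerPool
from .errors import ModelError, SimulationError
from .index import ProductRecord, build_product_index
from .model import ConstitutiveBlock, GeneModel, Variant, VariantRegion
from .thermo import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

COGNATE = "cognate"
NEAR_COGNATE = "near_cognate"
SWITCHED = "switched"


@dataclass(frozen=True)
class SimConfig:
    """One simulated experiment.

    proportions : isoform key -> relative weight (need not sum to 1).
    switch_rate : probability a product is a cross-molecule (cross-pool)
        chimera.  near_cognate_rate : probability one variant ligamer is
        replaced by its nearest near-cognate.  read_length 250 nt paired;
    per_base_error : i.i.d. substitution probability.
    """

    seed: int
    n_molecules: int
    proportions: dict[str, float]
    switch_rate: float = 0.0
    near_cognate_rate: float = 0.0
    read_length: int = 250
    per_base_error: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.switch_rate, self.near_cognate_rate, self.per_base_error):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("rates must be in [0, 1]")
        if not self.proportions or all(w == 0 for w in self.proportions.values()):
            raise SimulationError("proportions must contain a nonzero weight")
        if any(w < 0 for w in self.proportions.values()):
            raise SimulationError("proportions must be nonnegative")


@dataclass(frozen=True)
class SimProduct:
    """One ligation product: concatenated ligamer chain from one (or, for a
    chimera, two) template molecules."""

    product_id: str
    sequence: str
    chain: tuple[tuple[str, str], ...]  # (pool_label, ligamer_id)
    pool_label: str


def random_dna(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _min_window_arm(seqs, lo: float = 55.0, hi: float = 65.0, min_len: int = 8) -> int | None:
    """Shortest anchored arm (prefix of seqs[0] / suffix of seqs[1]) whose Tm
    enters [lo, hi]; None if the window is never reached."""
    from .thermo import melting_temp

    best = None
    for anchor, seq in zip(("5p", "3p"), seqs):
        found = None
        for length in range(min_len, len(seq) + 1):
            cand = seq[:length] if anchor == "5p" else seq[len(seq) - length :]
            if lo <= melting_temp(cand) <= hi:
                found = length
                break
        if found is None:
            return None
        best = found if best is None else max(best, found)
    return best


def _designable(seq: str, max_min_arm: int = 23) -> bool:
    """True when both piece termini reach the internal-arm Tm window with an
    arm short enough that two arms plus a default barcode fit in 60 nt."""
    half = len(seq) // 2
    m = _min_window_arm((seq[:half], seq[half:]))
    return m is not None and m <= max_min_arm


def _draw_designable(length: int, rng: np.random.Generator, what: str, tries: int = 200) -> str:
    for _ in range(tries):
        seq = random_dna(length, rng)
        if _designable(seq):
            return seq
    raise SimulationError(f"could not draw a designable {what} of length {length}")


# ---------------------------------------------------------------------------
# gene synthesis
# ---------------------------------------------------------------------------


def synth_gene(
    n_clusters: int | None = None,
    variants_per_cluster: int | list[int] = 4,
    exon_length: int = 150,
    similarity: float = 0.8,
    seed: int = 0,
    block_length: int = 200,
    gene_id: str = "synth",
) -> GeneModel:
    """Random gene model: terminal blocks, cassette clusters, separating blocks.

    Variant exons within a cluster are derived from a cluster consensus:
    each position is forced to the consensus base with probability
    ``similarity`` and drawn uniformly otherwise, so the expected pairwise
    identity is ``s**2 + (1 - s**2)/4`` (0.25 for independent sequences,
    1.0 for identical variants).  Reproducible under ``seed``.
    """
    if not 0.0 <= similarity <= 1.0:
        raise SimulationError("similarity must be in [0, 1]")
    if exon_length < 16:
        raise SimulationError("exon_length must be >= 16 to fit two ligamer arms")
    if block_length < 16:
        raise SimulationError("block_length must be >= 16")
    sizes = (
        [variants_per_cluster] * (n_clusters or 1)
        if isinstance(variants_per_cluster, int)
        else list(variants_per_cluster)
    )
    if n_clusters is not None and len(sizes) != n_clusters:
        raise SimulationError("variants_per_cluster length must match n_clusters")
    rng = np.random.default_rng(seed)
    regions: list = [ConstitutiveBlock("b0", _draw_designable(block_length, rng, "block"))]
    for ci, size in enumerate(sizes, start=1):
        consensus = np.frombuffer(
            _draw_designable(exon_length, rng, "cluster consensus").encode(), dtype=np.uint8
        )
        variants = []
        for vi in range(1, size + 1):
            for _ in range(200):
                keep = rng.random(exon_length) < similarity
                rand = _BASES[rng.integers(0, 4, size=exon_length)]
                seq = np.where(keep, consensus, rand).tobytes().decode()
                if _designable(seq):
                    break
            else:
                raise SimulationError(
                    f"exon_length {exon_length} too short to draw designable variants"
                )
            variants.append(Variant(f"c{ci}.{vi}", seq))
        regions.append(VariantRegion(f"c{ci}", "cassette", tuple(variants)))
        regions.append(ConstitutiveBlock(f"b{ci}", _draw_designable(block_length, rng, "block")))
    return GeneModel(gene_id=gene_id, regions=tuple(regions))


def dscam_like_model(seed: int = 0, four_clusters: bool = False, exon_length: int = 150) -> GeneModel:
    """Synthetic model with the Dscam1 cluster architecture.

    Three mutually exclusive clusters of 12, 48 and 33 variants between
    terminal and separating constitutive blocks (the profiled exon 3–10
    span); with ``four_clusters`` a fourth 2-variant cluster is appended,
    giving the full 12 x 48 x 33 x 2 = 38,016 isoform space.
    """
    sizes = [12, 48, 33, 2] if four_clusters else [12, 48, 33]
    return synth_gene(
        variants_per_cluster=sizes,
        exon_length=exon_length,
        similarity=0.8,
        seed=seed,
        gene_id="dscam_like",
    )


def fn1_like_model(seed: int = 0) -> GeneModel:
    """Synthetic model with the Fn1 EDA/V architecture.

    A cassette exon that can be included or skipped (EDA±) and an
    alternative 3' splice-site region with three outcomes (V120 / V95 /
    skip), separated by a constitutive block: 2 x 3 = 6 isoforms.  The V95
    outcome shares its 3' end with V120, as alternative acceptors do.
    """
    rng = np.random.default_rng(seed)
    for _ in range(200):
        v120 = random_dna(120, rng)
        v95 = v120[25:]  # promoter-distal acceptor: less 5' sequence, same 3' end
        if _designable(v120) and _designable(v95):
            break
    else:
        raise SimulationError("could not draw designable alt-3'SS variants")
    return GeneModel(
        gene_id="fn1_like",
        regions=(
            ConstitutiveBlock("b0", _draw_designable(80, rng, "block")),
            VariantRegion(
                "EDA", "cassette", (Variant("EDA+", _draw_designable(80, rng, "exon")), Variant("EDA-"))
            ),
            ConstitutiveBlock("b1", _draw_designable(400, rng, "block")),
            VariantRegion(
                "V", "alt3ss", (Variant("V120", v120), Variant("V95", v95), Variant("V0"))
            ),
            ConstitutiveBlock("b2", _draw_designable(80, rng, "block")),
        ),
    )


def loopout_demo(seed: int = 0) -> tuple[GeneModel, LigamerPool]:
    """Minimal loop-out compression demonstration.

    A single 307-nt constitutive transcript covered by four 26-nt ligamers
    (10-nt arms flanking a 6-nt spacer, no primer tails), each looping out
    part of the template.  The chain spans 244 nt of RNA (eight 10-nt
    footprints plus loops of 35/40/45/44 nt) and condenses it into a 104-nt
    ligation product — a 2.35-fold compression.
    """
    from .design import INTERNAL, Ligamer, LigamerPool

    rng = np.random.default_rng(seed)
    template = random_dna(307, rng)
    model = GeneModel(gene_id="loopout_demo", regions=(ConstitutiveBlock("t", template),))
    # footprints: up arm, loop, down arm; consecutive ligamers abut exactly
    windows = [(20, 30, 65, 75), (75, 85, 125, 135), (135, 145, 190, 200), (200, 210, 254, 264)]
    spacers = ["ACGTAC", "TGCATG", "CTAGCT", "GATCGA"]
    ligamers = []
    for i, ((u0, u1, d0, d1), spacer) in enumerate(zip(windows, spacers), start=1):
        ligamers.append(
            Ligamer(
                id=f"L{i}",
                kind=INTERNAL,
                arm_up=template[u0:u1],
                arm_down=template[d0:d1],
                spacer=spacer,
                target_coords=(("t", u0, u1), ("t", d0, d1)),
                has_5p_phosphate=(i > 1),
            )
        )
    adjacency = tuple((a.id, b.id) for a, b in zip(ligamers, ligamers[1:]))
    pool = LigamerPool(gene_id="loopout_demo", ligamers=tuple(ligamers), adjacency=adjacency)
    return model, pool


# ---------------------------------------------------------------------------
# mixtures and ligation
# ---------------------------------------------------------------------------


def simulate_isoform_mix(
    model: GeneModel,
    proportions: dict[str, float],
    n_molecules: int,
    seed: int = 0,
) -> list[str]:
    """Multinomial draw of ``n_molecules`` isoform keys at the given weights."""
    known = set(model.isoform_keys(include_excluded=True))
    unknown = set(proportions) - known
    if unknown:
        raise ModelError(f"unknown isoform keys in proportions: {sorted(unknown)[:5]}")
    keys = sorted(proportions)
    w = np.array([proportions[k] for k in keys], dtype=float)
    if w.sum() <= 0 or (w < 0).any():
        raise SimulationError("proportions must be nonnegative with positive sum")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_molecules, w / w.sum())
    out: list[str] = []
    for k, c in zip(keys, counts):
        out.extend([k] * int(c))
    rng.shuffle(out)  # molecule order independent of key order
    return out


def _nearest_near_cognate_map(
    model: GeneModel, pool: LigamerPool
) -> dict[str, str]:
    """variant id -> id of its nearest near-cognate sibling by arm ΔG.

    For each variant v, every sibling ligamer w is scored by the free energy
    of w's arms against v's exon; the most stable competitor (minimum ΔG,
    ties broken lexicographically) is v's nearest near-cognate.
    """
    from .design import ligamer_target_dg

    by_id = pool.by_id
    out: dict[str, str] = {}
    for region in model.variant_regions:
        vids = [v.id for v in region.variants if not v.is_skip]
        seqs = {v.id: v.sequence or "" for v in region.variants if not v.is_skip}
        if len(vids) < 2:
            continue
        for v in vids:
            scored = sorted(
                (ligamer_target_dg(by_id[w], seqs[v]), w) for w in vids if w != v and w in by_id
            )
            if scored:
                out[v] = scored[0][1]
    return out


def simulate_ligation(
    molecules: list[str],
    model: GeneModel,
    pools: LigamerPool | tuple[LigamerPool, LigamerPool],
    switch_rate: float = 0.0,
    near_cognate_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SimProduct], pd.DataFrame]:
    """Ligate each template molecule into a product, with artifact modes.

    Each molecule is assigned a pool (uniformly, if a dual pool is given)
    and normally yields the cognate chain for its isoform.  With probability
    ``switch_rate`` the product is a chimera: its suffix chain is taken from
    another molecule (of the other pool in dual mode), with the single
    crossover at a uniformly chosen separating constitutive block — the
    shared-sequence context where template exchange happens.  With
    probability ``near_cognate_rate`` one variant ligamer is replaced by its
    nearest near-cognate sibling (smallest arm-ΔG gap), so the product reads
    as the wrong, but valid, isoform.  Returns the products and a truth
    ledger with one row per product.
    """
    dual = isinstance(pools, tuple)
    pool_list = list(pools) if dual else [pools]
    rng = np.random.default_rng(seed)
    if switch_rate > 0:
        seps = [
            r.id
            for r in model.regions[1:-1]
            if isinstance(r, ConstitutiveBlock)
        ]
        if not seps:
            raise SimulationError(
                "template switching needs at least one separating constitutive block"
            )
    indexes = [
        {r.isoform_key: r for r in build_product_index(model, p, include_excluded=True)}
        for p in pool_list
    ]
    near_map = _nearest_near_cognate_map(model, pool_list[0]) if near_cognate_rate > 0 else {}
    vregion_order = [r.id for r in model.variant_regions]

    n = len(molecules)
    pool_of = rng.integers(0, len(pool_list), size=n)
    u = rng.random(n)

    products: list[SimProduct] = []
    truth_rows: list[dict] = []
    for i, key in enumerate(molecules):
        pi = int(pool_of[i])
        pool = pool_list[pi]
        record = indexes[pi][key]
        artifact = COGNATE
        secondary = ""
        if u[i] < switch_rate:
            artifact = SWITCHED
            # partner from the other pool (dual) or any other molecule
            for _ in range(1000):
                j = int(rng.integers(0, n))
                if j != i and (not dual or pool_of[j] != pi):
                    break
            else:
                raise SimulationError("could not draw a switch partner")
            pj = int(pool_of[j])
            rec_b = indexes[pj][molecules[j]]
            cut_block = str(rng.choice([
                r.id for r in model.regions[1:-1] if isinstance(r, ConstitutiveBlock)
            ]))
            ca = list(record.ligamer_chain)
            cb = list(rec_b.ligamer_chain)
            cut_a = ca.index(cut_block) + 1  # block ligamer stays with the prefix
            cut_b = cb.index(cut_block) + 1
            chain = [(pool.pool_label, lid) for lid in ca[:cut_a]] + [
                (pool_list[pj].pool_label, lid) for lid in cb[cut_b:]
            ]
            seq = "".join(pool.by_id[lid].sequence for lid in ca[:cut_a]) + "".join(
                pool_list[pj].by_id[lid].sequence for lid in cb[cut_b:]
            )
            secondary = molecules[j]
        elif u[i] < switch_rate + near_cognate_rate and near_map:
            # pick a substitutable variant position
            choices = [vid for vid in key.split("|") if vid in near_map]
            if choices:
                artifact = NEAR_COGNATE
                vid = str(rng.choice(choices))
                sub = near_map[vid]
                parts = key.split("|")
                parts[parts.index(vid)] = sub
                alt_key = "|".join(parts)
                alt = indexes[pi][alt_key]
                chain = [(pool.pool_label, lid) for lid in alt.ligamer_chain]
                seq = alt.product_sequence
                secondary = alt_key
            else:
                chain = [(pool.pool_label, lid) for lid in record.ligamer_chain]
                seq = record.product_sequence
        if artifact == COGNATE:
            chain = [(pool.pool_label, lid) for lid in record.ligamer_chain]
            seq = record.product_sequence
        pid_str = f"mol{i:07d}"
        products.append(
            SimProduct(
                product_id=pid_str,
                sequence=seq,
                chain=tuple(chain),
                pool_label=pool.pool_label,
            )
        )
        truth_rows.append(
            {
                "product_id": pid_str,
                "true_key": key,
                "pool_label": pool.pool_label,
                "artifact": artifact,
                "secondary_key": secondary,
            }
        )
    return products, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: r1 = 5' prefix of the product, r2 = reverse
    complement of its 3' suffix; constant base quality."""

    read_id: str
    r1: str
    r2: str


def simulate_reads(
    products: list[SimProduct],
    read_length: int = 250,
    per_base_error: float = 0.0,
    seed: int = 0,
) -> list[ReadPair]:
    """Paired reads from each product with i.i.d. substitution errors.

    Mates overlap whenever the product is shorter than twice the read
    length (overlap = 2*read_length - product_length); products at least
    that long trigger a warning since their middles go unread.
    """
    if not products:
        raise SimulationError("empty product set")
    import warnings

    rng = np.random.default_rng(seed)
    long_products = sum(1 for p in products if len(p.sequence) >= 2 * read_length)
    if long_products:
        warnings.warn(
            f"{long_products} products are >= 2x read length; mates will not overlap",
            stacklevel=2,
        )
    out: list[ReadPair] = []
    for p in products:
        r1 = p.sequence[:read_length]
        r2 = reverse_complement(p.sequence)[:read_length]
        if per_base_error > 0:
            r1 = _mutate(r1, per_base_error, rng)
            r2 = _mutate(r2, per_base_error, rng)
        out.append(ReadPair(read_id=p.product_id, r1=r1, r2=r2))
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def write_paired_fastq(reads: list[ReadPair], r1_path, r2_path) -> None:
    """Write mates to two FASTQ files with constant 'I' qualities."""
    for path, attr, suffix in ((r1_path, "r1", "/1"), (r2_path, "r2", "/2")):
        with open(path, "w") as fh:
            fh.write(paired_fastq_text(reads, attr, suffix))


def paired_fastq_text(reads: list[ReadPair], attr: str, suffix: str) -> str:
    buf = io.StringIO()
    for r in reads:
        seq = getattr(r, attr)
        buf.write(f"@{r.read_id}{suffix}\n{seq}\n+\n{'I' * len(seq)}\n")
    return buf.getvalue()


def read_paired_fastq(r1_path, r2_path) -> list[ReadPair]:
    from Bio import SeqIO

    r1s = list(SeqIO.parse(str(r1_path), "fastq"))
    r2s = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1s) != len(r2s):
        raise SimulationError("mate files differ in read count")
    out = []
    for a, b in zip(r1s, r2s):
        out.append(ReadPair(read_id=a.id.rsplit("/", 1)[0], r1=str(a.seq), r2=str(b.seq)))
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimResult:
    products: list[SimProduct]
    truth: pd.DataFrame
    reads: list[ReadPair]


def run_simulation(
    model: GeneModel,
    pools: LigamerPool | tuple[LigamerPool, LigamerPool],
    config: SimConfig,
) -> SimResult:
    """Mixture -> ligation -> paired reads, all seeded from ``config.seed``."""
    molecules = simulate_isoform_mix(
        model, config.proportions, config.n_molecules, seed=config.seed
    )
    products, truth = simulate_ligation(
        molecules,
        model,
        pools,
        switch_rate=config.switch_rate,
        near_cognate_rate=config.near_cognate_rate,
        seed=config.seed + 1,
    )
    reads = simulate_reads(
        products,
        read_length=config.read_length,
        per_base_error=config.per_base_error,
        seed=config.seed + 2,
    )
    return SimResult(products=products, truth=truth, reads=reads)
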