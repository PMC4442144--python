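"""Gene models for ligamer design: ordered constitutive and variant regions.

A :class:`GeneModel` is an ordered 5'->3' list of transcript regions:

* constitutive blocks — sequence present in every isoform;
* cassette clusters — mutually exclusive variant exons, exactly one chosen
  per mRNA (a skip outcome, where no exon is included, is representable as a
  variant with no sequence);
* alternative 3' splice-site regions — competing acceptor outcomes that
  include different amounts of sequence, again with an optional skip.

An isoform is one choice per variant region; its key is the ``|``-joined
list of chosen variant ids in transcript order (e.g. ``"4.3|6.12|9.30"``).
Variants can carry an ``excluded`` flag (e.g. an annotated pseudo-exon) so
both the full and the reduced isoform space can be enumerated.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import ModelError

_DNA = frozenset("ACGT")


def _clean_seq(seq: str, where: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= _DNA:
        raise ModelError(f"{where}: sequence must be ACGT/ACGU")
    return seq


@dataclass(frozen=True)
class ConstitutiveBlock:
    """A run of constitutively included sequence (one or several exons)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean_seq(self.sequence, f"block {self.id}"))


@dataclass(frozen=True)
class Variant:
    """One outcome of a variant region.

    ``sequence=None`` encodes the skip outcome (no exon included);
    ``excluded=True`` drops the variant from default isoform enumeration
    while keeping it designable/indexable.
    """

    id: str
    sequence: str | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.sequence is not None:
            object.__setattr__(
                self, "sequence", _clean_seq(self.sequence, f"variant {self.id}")
            )

    @property
    def is_skip(self) -> bool:
        return self.sequence is None


@dataclass(frozen=True)
class VariantRegion:
    """A mutually exclusive choice point: cassette cluster or alt-3'SS region."""

    id: str
    kind: str  # "cassette" | "alt3ss"
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("cassette", "alt3ss"):
            raise ModelError(f"region {self.id}: unknown kind {self.kind!r}")
        object.__setattr__(self, "variants", tuple(self.variants))
        if not self.variants:
            raise ModelError(f"region {self.id}: empty variant list")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ModelError(f"region {self.id}: duplicate variant ids")

    def choices(self, include_excluded: bool = False) -> tuple[Variant, ...]:
        out = tuple(v for v in self.variants if include_excluded or not v.excluded)
        if not out:
            raise ModelError(f"region {self.id}: no selectable variants")
        return out


Region = ConstitutiveBlock | VariantRegion


@dataclass(frozen=True)
class GeneModel:
    """Ordered transcript regions of one gene, 5'->3'."""

    gene_id: str
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if not self.regions:
            raise ModelError("gene model has no regions")
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate region ids")

    @property
    def variant_regions(self) -> tuple[VariantRegion, ...]:
        return tuple(r for r in self.regions if isinstance(r, VariantRegion))

    @property
    def blocks(self) -> tuple[ConstitutiveBlock, ...]:
        return tuple(r for r in self.regions if isinstance(r, ConstitutiveBlock))

    # -- isoforms ----------------------------------------------------------

    def isoform_keys(self, include_excluded: bool = False) -> list[str]:
        """All isoform keys, lexicographically ordered.

        The count is the product over variant regions of the number of
        selectable outcomes (a skip counts as one outcome).  A model with no
        variant regions has the single key ``""``.
        """
        vregions = self.variant_regions
        if not vregions:
            return [""]
        pools = [[v.id for v in r.choices(include_excluded)] for r in vregions]
        keys = ["|".join(combo) for combo in itertools.product(*pools)]
        return sorted(keys)

    def choices_from_key(self, key: str) -> dict[str, Variant]:
        """Map region id -> chosen Variant for an isoform key."""
        vregions = self.variant_regions
        parts = key.split("|") if key else []
        if len(parts) != len(vregions):
            raise ModelError(
                f"key {key!r} has {len(parts)} choices for {len(vregions)} variant regions"
            )
        out: dict[str, Variant] = {}
        for region, vid in zip(vregions, parts):
            match = [v for v in region.variants if v.id == vid]
            if not match:
                raise ModelError(f"key {key!r}: no variant {vid!r} in region {region.id}")
            out[region.id] = match[0]
        return out

    def isoform_pieces(self, key: str) -> list[tuple[str, str]]:
        """Ordered (piece_id, sequence) making up one isoform.

        Blocks contribute under their region id, variant regions under the
        chosen variant id; skip outcomes contribute an empty sequence.
        """
        chosen = self.choices_from_key(key)
        pieces: list[tuple[str, str]] = []
        for region in self.regions:
            if isinstance(region, ConstitutiveBlock):
                pieces.append((region.id, region.sequence))
            else:
                v = chosen[region.id]
                pieces.append((v.id, v.sequence or ""))
        return pieces

    def isoform_sequence(self, key: str) -> str:
        return "".join(seq for _, seq in self.isoform_pieces(key))

    def isoform_layout(self, key: str) -> dict[str, int]:
        """Piece id -> start offset of that piece within the isoform sequence."""
        layout: dict[str, int] = {}
        pos = 0
        for pid, seq in self.isoform_pieces(key):
            layout[pid] = pos
            pos += len(seq)
        return layout

    def with_excluded(self, variant_ids: set[str] | list[str]) -> "GeneModel":
        """Copy of the model with the named variants flagged ``excluded``."""
        wanted = set(variant_ids)
        regions: list[Region] = []
        for region in self.regions:
            if isinstance(region, VariantRegion):
                vs = tuple(
                    replace(v, excluded=True) if v.id in wanted else v
                    for v in region.variants
                )
                regions.append(replace(region, variants=vs))
            else:
                regions.append(region)
        return replace(self, regions=tuple(regions))

    # -- JSON --------------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def region_dict(r: Region) -> dict:
            if isinstance(r, ConstitutiveBlock):
                return {"type": "constitutive", "id": r.id, "sequence": r.sequence}
            return {
                "type": r.kind,
                "id": r.id,
                "variants": [
                    {
                        "id": v.id,
                        **({"sequence": v.sequence} if v.sequence is not None else {"skip": True}),
                        **({"excluded": True} if v.excluded else {}),
                    }
                    for v in r.variants
                ],
            }

        text = json.dumps(
            {"gene_id": self.gene_id, "regions": [region_dict(r) for r in self.regions]},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GeneModel":
        if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        regions: list[Region] = []
        for rd in data["regions"]:
            if rd["type"] == "constitutive":
                regions.append(ConstitutiveBlock(rd["id"], rd["sequence"]))
            else:
                variants = tuple(
                    Variant(
                        vd["id"],
                        sequence=None if vd.get("skip") else vd["sequence"],
                        excluded=bool(vd.get("excluded", False)),
                    )
                    for vd in rd["variants"]
                )
                regions.append(VariantRegion(rd["id"], rd["type"], variants))
        return cls(gene_id=data["gene_id"], regions=tuple(regions))
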