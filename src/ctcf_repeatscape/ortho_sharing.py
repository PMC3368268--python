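"""Cross-species interval projection through an alignment block map.

The block map is the desk-scale stand-in for a multiple sequence alignment:
colinear, indel-free segments ("blocks") with one coordinate row per species
that contains the block.  Because evolution inside blocks is substitution-only,
segment lengths are equal across species within a block and projection is
exact coordinate arithmetic.  Species-specific insertions (e.g. new repeat
copies) are blocks with a single species row and project nowhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import merge, overlaps_any

#: fixed species order used by sharing codes ("11111" = five-way shared,
#: "00110" = mouse-rat only)
CODE_SPECIES = ("human", "macaque", "mouse", "rat", "dog")
ALL_SPECIES = CODE_SPECIES + ("opossum",)

BLOCKMAP_COLUMNS = ["block_id", "species", "chrom", "start", "end", "strand"]


class BlockMapError(ValueError):
    pass


class BlockMap:
    """Cross-species coordinate correspondence in alignment blocks."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in BLOCKMAP_COLUMNS if c not in df.columns]
        if missing:
            raise BlockMapError(f"block map missing columns: {missing}")
        df = df[BLOCKMAP_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        lengths = df.assign(length=df["end"] - df["start"]).groupby("block_id")["length"]
        if (lengths.nunique() > 1).any():
            bad = lengths.nunique()
            raise BlockMapError(
                f"segment length mismatch within blocks: {list(bad[bad > 1].index[:5])}"
            )
        if (df["end"] <= df["start"]).any():
            raise BlockMapError("blocks must have positive length")
        self.df = df
        # per-species sorted lookup tables
        self._by_species: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        self._rows: dict[tuple[str, str], tuple[str, int, int, str]] = {}
        for (sp, chrom), sub in df.groupby(["species", "chrom"]):
            sub = sub.sort_values("start")
            s = sub["start"].to_numpy()
            if np.any(s[1:] < sub["end"].to_numpy()[:-1]):
                raise BlockMapError(f"overlapping blocks within {sp}:{chrom}")
            self._by_species.setdefault(sp, {})[chrom] = {
                "start": s,
                "end": sub["end"].to_numpy(),
                "strand": sub["strand"].to_numpy(),
                "block_id": sub["block_id"].to_numpy(),
            }
        for row in df.itertuples(index=False):
            self._rows[(row.block_id, row.species)] = (row.chrom, row.start, row.end, row.strand)

    @property
    def species(self) -> list[str]:
        return sorted(self._by_species)

    def chrom_tables(self, species: str) -> dict[str, dict[str, np.ndarray]]:
        return self._by_species.get(species, {})

    def project(
        self,
        interval: tuple[str, int, int],
        source: str,
        target: str,
    ) -> list[tuple[str, int, int]] | None:
        """Map an interval from source to target species; None if unalignable.

        Offsets within a block are measured along the block axis (reversed for
        '-' strand rows); abutting projected pieces are merged.
        """
        chrom, start, end = interval
        tables = self._by_species.get(source, {}).get(chrom)
        if tables is None:
            return None
        s, e = tables["start"], tables["end"]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        pieces: list[tuple[str, int, int]] = []
        for i in range(lo, hi):
            a, b = max(start, s[i]), min(end, e[i])
            if b <= a:
                continue
            # block-axis offsets of the piece
            if tables["strand"][i] == "+":
                o1, o2 = a - s[i], b - s[i]
            else:
                o1, o2 = e[i] - b, e[i] - a
            trow = self._rows.get((tables["block_id"][i], target))
            if trow is None:
                continue
            tchrom, ts, te, tstrand = trow
            if tstrand == "+":
                pieces.append((tchrom, ts + o1, ts + o2))
            else:
                pieces.append((tchrom, te - o2, te - o1))
        if not pieces:
            return None
        out: list[tuple[str, int, int]] = []
        for tchrom in sorted({p[0] for p in pieces}):
            ps = [p for p in pieces if p[0] == tchrom]
            ms, me = merge(
                np.array([p[1] for p in ps]), np.array([p[2] for p in ps])
            )
            out.extend((tchrom, int(a), int(b)) for a, b in zip(ms, me))
        return out

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BlockMap":
        return cls(pd.read_csv(path, sep="\t"))


def _projection_overlaps(
    pieces: list[tuple[str, int, int]] | None, events: pd.DataFrame
) -> bool:
    if not pieces or events.empty:
        return False
    for chrom, a, b in pieces:
        sub = events[events["chrom"] == chrom]
        if sub.empty:
            continue
        if overlaps_any(
            np.array([a]), np.array([b]), sub["start"].to_numpy(), sub["end"].to_numpy()
        )[0]:
            return True
    return False


def sharing_code(
    event: tuple[str, int, int],
    events_by_species: dict[str, pd.DataFrame],
    block_map: BlockMap,
    anchor: str,
    species_order: tuple[str, ...] = CODE_SPECIES,
    require_alignable: bool = True,
) -> str | None:
    """Binary sharing code over ``species_order`` for one anchored event.

    Bit i is 1 iff the event's projection into species i overlaps (>= 1 bp) a
    binding event there; the anchor bit is always 1.  With
    ``require_alignable`` (the default) an event projecting into no other
    species is excluded (returns None), mirroring the restriction of the
    evolutionary analysis to aligned genome regions.
    """
    if anchor not in species_order:
        raise ValueError(f"anchor {anchor!r} not in species order {species_order}")
    bits = []
    any_proj = False
    for sp in species_order:
        if sp == anchor:
            bits.append("1")
            continue
        pieces = block_map.project(event, anchor, sp)
        if pieces:
            any_proj = True
        bits.append("1" if _projection_overlaps(pieces, events_by_species.get(sp, pd.DataFrame(columns=["chrom", "start", "end"]))) else "0")
    if require_alignable and not any_proj:
        return None
    return "".join(bits)


def sharing_codes(
    events: pd.DataFrame,
    events_by_species: dict[str, pd.DataFrame],
    block_map: BlockMap,
    anchor: str,
    species_order: tuple[str, ...] = CODE_SPECIES,
    require_alignable: bool = True,
) -> pd.Series:
    """Sharing code per event row (None where excluded as unalignable)."""
    codes = []
    for row in events.itertuples(index=False):
        codes.append(
            sharing_code(
                (row.chrom, int(row.start), int(row.end)),
                events_by_species,
                block_map,
                anchor,
                species_order,
                require_alignable,
            )
        )
    return pd.Series(codes, index=events.index, dtype=object)


def pairwise_shared_percent(
    species_a: str,
    species_b: str,
    events_by_species: dict[str, pd.DataFrame],
    block_map: BlockMap,
) -> float | None:
    """Directional-average shared percentage between two species.

    mean( shared A->B / alignable A, shared B->A / alignable B ) * 100, where
    an event is alignable if >= 1 bp projects into the other species and
    shared if its projection overlaps an event there.  ``None`` when either
    species has no alignable events.
    """
    fracs = []
    for src, tgt in ((species_a, species_b), (species_b, species_a)):
        n_align = n_shared = 0
        tgt_events = events_by_species[tgt]
        for row in events_by_species[src].itertuples(index=False):
            pieces = block_map.project((row.chrom, int(row.start), int(row.end)), src, tgt)
            if not pieces:
                continue
            n_align += 1
            if _projection_overlaps(pieces, tgt_events):
                n_shared += 1
        if n_align == 0:
            return None
        fracs.append(n_shared / n_align)
    return 100.0 * float(np.mean(fracs))


def five_way_fraction(codes: pd.Series) -> float:
    """Fraction of (alignable) events shared in all code species."""
    valid = codes.dropna()
    if valid.empty:
        return float("nan")
    full = "1" * len(CODE_SPECIES)
    return float((valid == full).mean())
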