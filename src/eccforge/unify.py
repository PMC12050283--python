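"""Cross-sample eccDNA identity unification.

Loci from different samples (and within one sample) receive the same
unified ID when they overlap by more than a threshold (default 200 bp,
strict).  "Same ID" is an equivalence relation, so merging is transitive:
unified IDs are the connected components of the pairwise-overlap graph.
Original locus coordinates are preserved unaltered; the unified region is
the coordinate hull of its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .caller import EccLocus


@dataclass
class SampleLocusSet:
    sample_id: str
    loci: list[EccLocus]

    def validate(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate locus_id in sample {self.sample_id!r}")


@dataclass
class UnifiedCatalog:
    """Partition of all input loci into unified IDs."""

    id_map: dict[tuple[str, str], str]  # (sample_id, locus_id) -> unified_id
    regions: pd.DataFrame  # unified_id, chrom, start, end, n_members + read sums
    sample_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.regions)


def unify_ids(sets: list[SampleLocusSet], min_overlap_bp: int = 200) -> UnifiedCatalog:
    """Merge loci overlapping by strictly more than `min_overlap_bp`.

    IDs are named ecc_000001... in (chrom, min start) order of the unified
    regions.
    """
    if not sets:
        raise ValueError("at least one sample locus set is required")
    for s in sets:
        s.validate()
    entries = []  # (chrom, start, end, n_reads, sample_id, locus_id)
    for s in sets:
        for locus in s.loci:
            entries.append((locus.chrom, locus.start, locus.end,
                            locus.n_reads, s.sample_id, locus.locus_id))
    entries.sort(key=lambda t: (t[0], t[1], t[2], t[4], t[5]))

    parent = list(range(len(entries)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # sweep within each chromosome; sorted by start, so once a later locus
    # starts beyond every earlier end minus the threshold, stop comparing
    i = 0
    n = len(entries)
    while i < n:
        chrom = entries[i][0]
        j = i
        while j < n and entries[j][0] == chrom:
            j += 1
        block = range(i, j)
        for a in block:
            _, sa, ea, *_ = entries[a]
            for b in range(a + 1, j):
                _, sb, eb, *_ = entries[b]
                if sb >= ea - min_overlap_bp:
                    break
                if min(ea, eb) - max(sa, sb) > min_overlap_bp:
                    union(a, b)
        i = j

    components: dict[int, list[int]] = {}
    for idx in range(n):
        components.setdefault(find(idx), []).append(idx)
    ordered = sorted(
        components.values(),
        key=lambda idxs: (entries[idxs[0]][0], min(entries[k][1] for k in idxs),
                          min(entries[k][2] for k in idxs)),
    )

    sample_ids = [s.sample_id for s in sets]
    id_map: dict[tuple[str, str], str] = {}
    rows = []
    for rank, idxs in enumerate(ordered):
        uid = f"ecc_{rank + 1:06d}"
        chrom = entries[idxs[0]][0]
        start = min(entries[k][1] for k in idxs)
        end = max(entries[k][2] for k in idxs)
        read_sums = dict.fromkeys(sample_ids, 0)
        for k in idxs:
            _, _, _, n_reads, sample_id, locus_id = entries[k]
            id_map[(sample_id, locus_id)] = uid
            read_sums[sample_id] += n_reads
        row = {"unified_id": uid, "chrom": chrom, "start": start, "end": end,
               "n_members": len(idxs)}
        row.update({f"reads_{sid}": read_sums[sid] for sid in sample_ids})
        rows.append(row)
    regions = pd.DataFrame(rows).set_index("unified_id")
    return UnifiedCatalog(id_map, regions, sample_ids)


def catalog_counts(catalog: UnifiedCatalog) -> pd.DataFrame:
    """Unified-ID x sample matrix of summed read support (absent = 0)."""
    cols = {f"reads_{sid}": sid for sid in catalog.sample_ids}
    return catalog.regions[list(cols)].rename(columns=cols)
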