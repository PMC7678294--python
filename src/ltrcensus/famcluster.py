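"""Family grouping of detected elements, consensi, and superfamily calls.

Elements are grouped the way a dot-plot comparison groups them: two
sequences look alike when they share many words.  ``pairwise_similarity``
quantifies that as the fraction of one sequence's words found in the
other's word set (both strands, symmetrised), and families are the
connected components of the >= threshold similarity graph (single
linkage).  Superfamily (gypsy vs copia) is decided by the order of the
reverse transcriptase and integrase domains in the pol polyprotein.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib

from ltrcensus._seq import word_set


@dataclass(frozen=True)
class DomainAnnotation:
    """Ordered pol-domain labels (PR, RT, RH, INT) with start coordinates."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        starts = [s for _, s in self.entries]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("domain starts must be strictly increasing")

    def start_of(self, label: str) -> int | None:
        for lab, s in self.entries:
            if lab == label:
                return s
        return None


@dataclass
class Family:
    family_id: str
    member_ids: list[str]
    consensus: str
    superfamily: str = "unknown"

    @property
    def n_elements(self) -> int:
        return len(self.member_ids)


def pairwise_similarity(a: str, b: str, word: int = 12) -> float:
    """Shared-word fraction between two sequences, in [0, 1].

    The fraction of a's word positions whose word occurs anywhere in b (on
    either strand), averaged with the reverse direction so the measure is
    symmetric.  This is the quantitative surrogate for judging a dot plot:
    dense off-diagonal word matches mean high similarity.
    """
    if len(a) < word or len(b) < word:
        raise ValueError("both sequences must be at least `word` long")
    return (_containment(a, b, word) + _containment(b, a, word)) / 2


def _containment(a: str, b: str, word: int) -> float:
    bwords = word_set(b, word, both_strands=True)
    n = len(a) - word + 1
    hits = sum(1 for i in range(n) if a[i : i + word] in bwords)
    return hits / n


def cluster_elements(
    elements: list[tuple[str, str]],
    threshold: float = 0.5,
    word: int = 12,
    domains: dict[str, DomainAnnotation] | None = None,
) -> list[Family]:
    """Single-linkage clustering of (id, sequence) pairs into families.

    Two elements are connected iff their pairwise similarity reaches the
    threshold; families are the connected components, ordered by size
    descending then by smallest member id.  Each family carries a
    majority-vote consensus; when per-member domain annotations are given
    the family superfamily is the majority vote of its members' calls.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if not elements:
        return []

    ids = [eid for eid, _ in elements]
    seqs = dict(elements)
    parent = {eid: eid for eid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (id_a, seq_a) in enumerate(elements):
        for id_b, seq_b in elements[i + 1 :]:
            if find(id_a) == find(id_b):
                continue
            if pairwise_similarity(seq_a, seq_b, word) >= threshold:
                parent[find(id_b)] = find(id_a)

    components: dict[str, list[str]] = {}
    for eid in ids:
        components.setdefault(find(eid), []).append(eid)
    ordered = sorted(components.values(), key=lambda m: (-len(m), min(m)))

    families = []
    for n, members in enumerate(ordered, 1):
        members = sorted(members)
        fam = Family(
            family_id=f"family{n}",
            member_ids=members,
            consensus=build_consensus([seqs[m] for m in members]),
        )
        if domains:
            calls = Counter(
                classify_superfamily(domains[m]) for m in members if m in domains
            )
            calls.pop("unknown", None)
            if calls:
                fam.superfamily = calls.most_common(1)[0][0]
        families.append(fam)
    return families


def build_consensus(members: list[str]) -> str:
    """Majority-vote consensus from a star alignment to the longest member.

    Each member is globally aligned to the longest member (the star
    centre); every centre column takes the majority base over the aligned
    member characters (ties broken alphabetically), and columns where a
    deletion wins are dropped, so the consensus is never longer than the
    centre.
    """
    if not members:
        raise ValueError("consensus of an empty family is undefined")
    if len(members) == 1:
        return members[0]
    center = max(members, key=len)
    columns: list[Counter] = [Counter() for _ in center]
    for m in members:
        res = edlib.align(m, center, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, m, center)
        ci = 0
        for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc == "-":
                continue  # insertion relative to the centre: ignored
            columns[ci][qc] += 1
            ci += 1
    out = []
    for col in columns:
        best_base = min(
            (b for b in "ACGT" if col[b]), key=lambda b: (-col[b], b), default=None
        )
        if best_base is None or col["-"] > col[best_base]:
            continue
        out.append(best_base)
    return "".join(out)


def classify_superfamily(domains: DomainAnnotation) -> str:
    """gypsy if integrase lies downstream of reverse transcriptase in pol,
    copia if upstream, unknown when either domain is missing."""
    rt = domains.start_of("RT")
    integrase = domains.start_of("INT")
    if rt is None or integrase is None:
        return "unknown"
    return "gypsy" if integrase > rt else "copia"


# ---------------------------------------------------------------------------
# writers


def families_to_tsv(families: list[Family], extra: dict[str, dict] | None = None) -> str:
    """Family table: name, member count, consensus length, superfamily.

    ``extra`` may map family_id to dicts with ltr_length / cds_length taken
    from the detected members (the per-family representative lengths)."""
    lines = ["family\tn_elements\ttotal_length\tltr_length\tcds_length\tsuperfamily"]
    for f in families:
        info = (extra or {}).get(f.family_id, {})
        lines.append(
            "\t".join(
                [
                    f.family_id,
                    str(f.n_elements),
                    str(len(f.consensus)),
                    str(info.get("ltr_length", "")),
                    str(info.get("cds_length", "")),
                    f.superfamily,
                ]
            )
        )
    return "\n".join(lines) + "\n"
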