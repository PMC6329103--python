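"""Protein sequence features: motif scanners, structure mapping, in-silico PCR.

The NLS/NES scanners are deliberately simple consensus implementations:

* bipartite NLS — two basic (K/R) clusters separated by a short spacer;
* leucine-rich NES — Phi1-x(2,3)-Phi2-x(2,3)-Phi3-x-Phi4 with
  Phi in {L, I, V, F, M}.

They are *not* re-implementations of external predictors (cNLS Mapper,
NetNES); externally predicted coordinates should be carried as plain
:class:`SequenceFeature` annotations (see :data:`EIF2A_FEATURES` for the
bundled human eIF2-alpha set).

The cloning utilities anneal primers by exact 3' suffix match and measure
restriction fragments on the top strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from ensdyn.ensemble_io import StructuralEnsemble

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
BASIC = frozenset("KR")
HYDROPHOBIC_PHI = frozenset("LIVFM")
DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FeatureKind(str, Enum):
    NLS_bipartite = "NLS_bipartite"
    NES = "NES"
    S1_domain = "S1_domain"
    phosphosite = "phosphosite"
    custom = "custom"


@dataclass(frozen=True)
class SequenceFeature:
    """An annotated span on a protein sequence; 1-based inclusive."""

    kind: FeatureKind
    start: int
    end: int
    score: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid span {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Human eIF2-alpha annotations from external predictors (cNLS Mapper with
#: cutoff 4, NetNES, site literature); carried as data, not recomputed.
EIF2A_FEATURES: tuple[SequenceFeature, ...] = (
    SequenceFeature(FeatureKind.NLS_bipartite, 182, 216, score=4.2, label="bipartite NLS"),
    SequenceFeature(FeatureKind.NES, 168, 168, label="NES anchor"),
    SequenceFeature(FeatureKind.phosphosite, 51, 51, label="S51"),
    SequenceFeature(FeatureKind.phosphosite, 158, 158, label="S158"),
)


def builtin_features(s1_span: tuple[int, int] | None = None) -> list[SequenceFeature]:
    """The bundled eIF2-alpha annotation set, optionally with an S1 span.

    The S1 (OB-fold) domain boundaries are not part of the bundled data and
    must be supplied by the caller.
    """
    feats = list(EIF2A_FEATURES)
    if s1_span is not None:
        feats.append(
            SequenceFeature(FeatureKind.S1_domain, s1_span[0], s1_span[1], label="S1 domain")
        )
    return feats


def _validate_protein(seq: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) - PROTEIN_ALPHABET)
    if bad:
        raise ValueError(f"invalid amino-acid characters: {''.join(bad)}")
    return seq


def _validate_dna(seq: str, allow_n: bool = False) -> str:
    seq = seq.upper()
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    bad = sorted(set(seq) - allowed)
    if bad:
        raise ValueError(f"invalid nucleotide characters: {''.join(bad)}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Motif scanners


def scan_bipartite_nls(
    seq: str,
    min_spacer: int = 9,
    max_spacer: int = 12,
    score_cutoff: float = 4.0,
) -> list[SequenceFeature]:
    """Scan for classical bipartite NLS motifs.

    A hit is two adjacent basic residues (K/R), a spacer of
    ``min_spacer..max_spacer`` arbitrary residues, then a 5-residue window
    containing at least 3 basics.  Score = basics in both clusters +
    0.5 * basics in the spacer; hits scoring below ``score_cutoff`` are
    dropped and overlapping hits are merged into the maximal-scoring span.
    Spans run from the first residue of cluster 1 to the last basic residue
    of cluster 2 (1-based inclusive).
    """
    seq = _validate_protein(seq)
    n = len(seq)
    basic = [c in BASIC for c in seq]
    hits: list[SequenceFeature] = []
    for i in range(n - 1):
        if not (basic[i] and basic[i + 1]):
            continue
        for spacer in range(min_spacer, max_spacer + 1):
            w = i + 2 + spacer  # start of the 5-residue second cluster
            if w + 5 > n:
                continue
            cluster2 = basic[w : w + 5]
            n2 = sum(cluster2)
            if n2 < 3:
                continue
            spacer_basics = sum(basic[i + 2 : w])
            score = 2 + n2 + 0.5 * spacer_basics
            if score < score_cutoff:
                continue
            last_basic = max(j for j in range(5) if cluster2[j])
            hits.append(
                SequenceFeature(
                    FeatureKind.NLS_bipartite,
                    start=i + 1,
                    end=w + last_basic + 1,
                    score=score,
                )
            )
    return _merge_overlapping(hits)


def _merge_overlapping(hits: list[SequenceFeature]) -> list[SequenceFeature]:
    """Merge overlapping hits, keeping the maximal-scoring span of each group."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda f: (f.start, f.end))
    merged: list[SequenceFeature] = []
    group: list[SequenceFeature] = [hits[0]]
    group_end = hits[0].end
    for h in hits[1:]:
        if h.start <= group_end:
            group.append(h)
            group_end = max(group_end, h.end)
        else:
            merged.append(max(group, key=lambda f: (f.score or 0, f.length)))
            group = [h]
            group_end = h.end
    merged.append(max(group, key=lambda f: (f.score or 0, f.length)))
    return merged


def scan_nes(seq: str) -> list[SequenceFeature]:
    """Scan for leucine-rich NES motifs: Phi1-x(2,3)-Phi2-x(2,3)-Phi3-x-Phi4.

    Phi in {L, I, V, F, M}.  One feature per distinct Phi1 position; among
    alternative gap combinations the smallest gaps win.  Span runs from
    Phi1 to Phi4.
    """
    seq = _validate_protein(seq)
    n = len(seq)
    phi = [c in HYDROPHOBIC_PHI for c in seq]
    out: list[SequenceFeature] = []
    for i in range(n):
        if not phi[i]:
            continue
        match_end = None
        for g1 in (2, 3):
            p2 = i + g1 + 1
            if p2 >= n or not phi[p2]:
                continue
            for g2 in (2, 3):
                p3 = p2 + g2 + 1
                p4 = p3 + 2
                if p4 < n and phi[p3] and phi[p4]:
                    match_end = p4
                    break
            if match_end is not None:
                break
        if match_end is not None:
            out.append(SequenceFeature(FeatureKind.NES, start=i + 1, end=match_end + 1))
    return out


# ---------------------------------------------------------------------------
# Mapping onto structures


@dataclass
class MappedFeature:
    feature: SequenceFeature
    resolved: list[int]
    missing: list[int]


def map_features_to_structure(
    features: Iterable[SequenceFeature],
    ensemble: StructuralEnsemble,
    chain: str | None = None,
) -> list[MappedFeature]:
    """Resolve feature spans to residue ids present in the structure.

    Features entirely outside the modeled range resolve empty (with a
    warning in ``missing``), not an error.
    """
    present = sorted(
        {a.resid for a in ensemble.atoms if chain is None or a.chain == chain}
    )
    present_set = set(present)
    out = []
    for f in features:
        span = range(f.start, f.end + 1)
        resolved = [r for r in span if r in present_set]
        missing = [r for r in span if r not in present_set]
        out.append(MappedFeature(feature=f, resolved=resolved, missing=missing))
    return out


# ---------------------------------------------------------------------------
# In-silico PCR and restriction digest


@dataclass(frozen=True)
class PcrProduct:
    """A double-stranded PCR product on a template top strand.

    ``start``/``end`` are the 1-based inclusive bounds of the annealed span
    on the template; unannealed 5' primer tails extend the product beyond
    that span.
    """

    start: int
    end: int
    fwd_tail_len: int
    rev_tail_len: int
    length: int
    sequence: str

    def __post_init__(self) -> None:
        expected = (self.end - self.start + 1) + self.fwd_tail_len + self.rev_tail_len
        if self.length != expected:
            raise ValueError(f"inconsistent product length {self.length} != {expected}")
        if len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with product length")


@dataclass(frozen=True)
class RestrictionSite:
    """Recognition sequence with top-strand cut offset (bases kept 5')."""

    name: str
    recognition: str
    cut_offset: int


HINDIII = RestrictionSite("HindIII", "AAGCTT", 1)  # A^AGCTT
XBAI = RestrictionSite("XbaI", "TCTAGA", 1)  # T^CTAGA

ENZYMES = {e.name.lower(): e for e in (HINDIII, XBAI)}


def _anneal_sites(primer: str, template: str, min_anneal: int) -> list[tuple[int, int]]:
    """(start_index, length) of maximal primer 3'-suffix matches on the template."""
    seed = primer[-min_anneal:]
    sites = []
    pos = template.find(seed)
    while pos != -1:
        # Extend the match towards the primer 5' end.
        length = min_anneal
        while (
            length < len(primer)
            and pos - (length - min_anneal) > 0
            and primer[-(length + 1)] == template[pos - (length - min_anneal) - 1]
        ):
            length += 1
        start = pos - (length - min_anneal)
        sites.append((start, length))
        pos = template.find(seed, pos + 1)
    return sites


def insilico_pcr(
    template: str, fwd: str, rev: str, min_anneal: int = 12
) -> list[PcrProduct]:
    """Amplify a linear template with two primers.

    A primer anneals wherever its longest 3' suffix (>= ``min_anneal``)
    matches exactly: the forward primer against the top strand, the reverse
    primer against the bottom strand.  Every forward site upstream of a
    reverse site yields one product; lengths include unannealed 5' tails.
    """
    template = _validate_dna(template, allow_n=True)
    fwd = _validate_dna(fwd)
    rev = _validate_dna(rev)
    for p, which in ((fwd, "forward"), (rev, "reverse")):
        if len(p) < min_anneal:
            raise ValueError(f"{which} primer shorter than min_anneal={min_anneal}")

    fwd_sites = _anneal_sites(fwd, template, min_anneal)
    # The reverse primer's 3' suffix pairs with the top strand such that
    # revcomp(suffix) appears as a prefix-anchored block on the top strand.
    rc_rev = revcomp(rev)
    rev_sites = []
    seed = rc_rev[:min_anneal]
    pos = template.find(seed)
    while pos != -1:
        length = min_anneal
        while (
            length < len(rev)
            and pos + length < len(template)
            and rc_rev[length] == template[pos + length]
        ):
            length += 1
        rev_sites.append((pos, length))
        pos = template.find(seed, pos + 1)

    products = []
    for fi, flen in fwd_sites:
        for ri, rlen in rev_sites:
            if fi > ri or fi + flen > ri + rlen:
                continue
            span = template[fi : ri + rlen]
            fwd_tail = len(fwd) - flen
            rev_tail = len(rev) - rlen
            seq = fwd[:fwd_tail] + span + revcomp(rev[:rev_tail])
            products.append(
                PcrProduct(
                    start=fi + 1,
                    end=ri + rlen,
                    fwd_tail_len=fwd_tail,
                    rev_tail_len=rev_tail,
                    length=len(span) + fwd_tail + rev_tail,
                    sequence=seq,
                )
            )
    return sorted(products, key=lambda p: (p.start, p.end))


def digest_fragment(
    product: PcrProduct,
    site5: RestrictionSite = HINDIII,
    site3: RestrictionSite = XBAI,
) -> int:
    """Top-strand length (bp) of the doubly-digested insert.

    Cuts after ``cut_offset`` bases of the 5'-most occurrence of ``site5``
    and of the 3'-most occurrence of ``site3``; the fragment spans the
    interval between the two cut positions.
    """
    seq = product.sequence
    p5 = seq.find(site5.recognition)
    if p5 == -1:
        raise ValueError(f"recognition site for {site5.name} not found in product")
    p3 = seq.rfind(site3.recognition)
    if p3 == -1:
        raise ValueError(f"recognition site for {site3.name} not found in product")
    cut5 = p5 + site5.cut_offset
    cut3 = p3 + site3.cut_offset
    fragment = cut3 - cut5
    if fragment <= 0:
        raise ValueError(
            f"{site3.name} cut is not downstream of the {site5.name} cut"
        )
    return fragment


# ---------------------------------------------------------------------------
# Writers


def features_to_tsv(features: Sequence[SequenceFeature], path: str | Path) -> Path:
    path = Path(path)
    lines = ["kind\tstart\tend\tscore\tlabel"]
    for f in features:
        score = "" if f.score is None else f"{f.score:g}"
        lines.append(f"{f.kind.value}\t{f.start}\t{f.end}\t{score}\t{f.label}")
    path.write_text("\n".join(lines) + "\n")
    return path


def features_to_bed(
    features: Sequence[SequenceFeature], path: str | Path, name: str = "seq"
) -> Path:
    """BED output: 1-based inclusive spans become 0-based half-open."""
    path = Path(path)
    lines = []
    for f in features:
        score = 0 if f.score is None else f.score
        lines.append(f"{name}\t{f.start - 1}\t{f.end}\t{f.kind.value}\t{score:g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_feature_table(path: str | Path) -> list[SequenceFeature]:
    """Read a TSV written by :func:`features_to_tsv`."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or (i == 0 and line.startswith("kind\t")):
            continue
        kind, start, end, score, label = (line.split("\t") + [""] * 5)[:5]
        out.append(
            SequenceFeature(
                FeatureKind(kind),
                int(start),
                int(end),
                score=float(score) if score else None,
                label=label,
            )
        )
    return out
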