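"""CDR3delta feature annotation and V(D)J junction decomposition.

Derives, per clonotype, the phosphoantigen-sensing determinants analysed
throughout the package:

* CDR3 length — junction length minus the two conserved anchors (C104 and
  F/W118), so a 14-residue junction string has CDR3 length 12;
* AA5 — the residue at CDR3 position 5 (IMGT 109), i.e. the 6th junction
  residue, and its membership in the hydrophobic set {A,V,L,I,P,W,F,M};
* invT — a template T at the second position of the codon encoding AA5
  (codon 6 of the junction), which restricts AA5 to {F,L,I,M,V};
* J region usage (J1..J4);
* N-insertion count from a maximum-germline-attribution decomposition of
  the junction into contiguous V / N1 / D / N2 / J blocks;
* the germline-encoded flag (zero unattributed nucleotides).

The decomposition uses exact, end-anchored matching only: palindromic (P)
nucleotides are not modelled separately and count as insertions, so
``germline_encoded`` means "decomposable with zero unattributed nt under
exact matching".
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineReference, j_region_of

__all__ = [
    "AnnotationError",
    "JunctionDecomposition",
    "HYDROPHOBIC_AA5",
    "INVT_AA5",
    "compute_cdr3_length",
    "extract_aa5",
    "decompose_junction",
    "classify_j_region_by_suffix",
    "detect_inv_t",
    "annotate_clonotypes",
]

#: Hydrophobic residues counted as hAA5 at CDR3 position 5.
HYDROPHOBIC_AA5 = frozenset("AVLIPWFM")

#: Residues whose codons carry T at the second position (invT-encodable).
INVT_AA5 = frozenset("FLIMV")


class AnnotationError(ValueError):
    """Input violates the preconditions of an annotation operation."""


@dataclass(frozen=True)
class JunctionDecomposition:
    """Attribution of junction nucleotides to V / N1 / D / N2 / J blocks.

    Block lengths always sum to the junction length; when no D segment is
    called the N nucleotides form one merged block reported as ``n1_len``.
    ``score`` is the number of germline-attributed nucleotides.
    """

    v_match_len: int
    n1_len: int
    d_segment: Optional[str]
    d_start_in_junction: int
    d_match_len: int
    n2_len: int
    j_match_len: int
    j_segment: Optional[str]

    @property
    def total_n(self) -> int:
        return self.n1_len + self.n2_len

    @property
    def score(self) -> int:
        return self.v_match_len + self.d_match_len + self.j_match_len

    @property
    def germline_encoded(self) -> bool:
        return self.total_n == 0


def compute_cdr3_length(junction_aa: str) -> int:
    """CDR3 length in amino acids: junction length minus the two anchors."""
    if len(junction_aa) < 3:
        raise AnnotationError(f"junction too short: {junction_aa!r}")
    if not junction_aa.startswith("C") or not junction_aa.endswith(("F", "W")):
        raise AnnotationError(f"junction lacks C.../F|W anchors: {junction_aa!r}")
    return len(junction_aa) - 2


def extract_aa5(junction_aa: str) -> Optional[tuple[str, bool]]:
    """Residue at CDR3 position 5 and its hydrophobicity flag.

    CDR3 position 5 is the 6th junction residue (the residue after C104
    counts as position 1).  Junctions shorter than 7 residues have no
    defined AA5 and return ``None`` (excluded from AA5 analyses).
    """
    if len(junction_aa) < 7:
        return None
    aa5 = junction_aa[5]
    return aa5, aa5 in HYDROPHOBIC_AA5


def detect_inv_t(
    junction_nt: str,
    junction_aa: str,
    decomposition: Optional["JunctionDecomposition"] = None,
    require_germline_origin: bool = False,
) -> bool:
    """True iff the second nucleotide of junction codon 6 (AA5's codon) is T.

    By default any T at that template position qualifies.  The stricter
    variant (``require_germline_origin=True``, results labelled as such)
    additionally requires the position to fall inside the decomposition's
    germline D block, i.e. the T must be D-segment encoded.
    """
    if len(junction_aa) < 7:
        raise AnnotationError("invT undefined for junctions shorter than 7 aa")
    if len(junction_nt) != 3 * len(junction_aa) or str(Seq(junction_nt).translate()) != junction_aa:
        raise AnnotationError("junction_nt is not a consistent in-frame encoding of junction_aa")
    has_t = junction_nt[16] == "T"  # codon 6 spans nt 16-18 (1-based), middle base
    if not has_t or not require_germline_origin:
        return has_t
    if decomposition is None:
        raise AnnotationError("require_germline_origin needs the junction decomposition")
    d_start = decomposition.d_start_in_junction
    return decomposition.d_match_len > 0 and d_start <= 16 < d_start + decomposition.d_match_len


def classify_j_region_by_suffix(
    junction_aa: str, reference: GermlineReference, min_overlap: int = 4
) -> Optional[str]:
    """J region whose translated head shares the longest suffix with the junction.

    Fallback used only when ``j_call`` is absent (an explicit call always
    takes precedence).  Returns ``None`` when no head overlaps by at least
    ``min_overlap`` residues; such clonotypes are excluded from J-usage
    statistics.
    """
    best: tuple[int, str] | None = None
    for region in reference.j_regions():
        head = reference.j_head_aa(region)
        k = 0
        while (
            k < min(len(head), len(junction_aa))
            and head[len(head) - 1 - k] == junction_aa[len(junction_aa) - 1 - k]
        ):
            k += 1
        if k >= min_overlap and (best is None or k > best[0]):
            best = (k, region)
    return best[1] if best else None


@lru_cache(maxsize=8)
def _d_seed_index(reference: GermlineReference, seed_len: int):
    """Seed-mer -> [(d_id, offset)] index over the reference D segments."""
    index: dict[str, list[tuple[str, int]]] = {}
    sequences: dict[str, str] = {}
    for d in reference.d_segments():
        sequences[d.segment_id] = d.nt_sequence
        for dj in range(len(d.nt_sequence) - seed_len + 1):
            index.setdefault(d.nt_sequence[dj : dj + seed_len], []).append((d.segment_id, dj))
    return index, sequences


def _longest_common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def decompose_junction(
    junction_nt: str,
    reference: GermlineReference,
    min_d_match: int = 3,
) -> JunctionDecomposition:
    """Maximum-germline-attribution decomposition of a junction.

    Searches over end-anchored exact V prefix matches, exact contiguous D
    substring matches of length >= ``min_d_match`` and end-anchored exact J
    suffix matches (best over the four J segments), maximising the number
    of germline-attributed nucleotides.  Ties are broken in favour of a
    larger V match, then a larger J match, then calling a D over no D, then
    the lexicographically smallest D id, then the leftmost D placement.
    Deterministic; the worst case is an all-N junction with score 0.
    """
    L = len(junction_nt)
    if L == 0:
        raise AnnotationError("empty junction")
    vreg = reference.v_junction_region()
    vmax = _longest_common_prefix(junction_nt, vreg)

    # Candidate J suffix matches; for a suffix length matched by several J
    # segments the lexicographically smallest region id is kept.
    j_options: list[tuple[int, Optional[str]]] = [(0, None)]
    seen_j_len: set[int] = set()
    for region in reference.j_regions():
        jreg = reference.j_junction_region(region)
        k = 0
        while k < min(len(jreg), L) and jreg[len(jreg) - 1 - k] == junction_nt[L - 1 - k]:
            k += 1
        for j_len in range(1, k + 1):
            if j_len not in seen_j_len:
                seen_j_len.add(j_len)
                j_options.append((j_len, f"TRDJ{region[-1]}*01"))

    # Maximal germline D-match intervals in the junction: any exact D match
    # inside a (V,J)-bounded window is the truncation of one of these, and a
    # truncated substring of a D segment is still a valid D match.  Matches
    # are located via a short-seed index over the D segments.
    seed_len = min(3, min_d_match)
    seed_index, d_sequences = _d_seed_index(reference, seed_len)
    per_d: dict[str, dict[int, int]] = {}  # d_id -> {start -> max end}
    for i in range(L - seed_len + 1):
        for d_id, dj in seed_index.get(junction_nt[i : i + seed_len], ()):
            d_nt = d_sequences[d_id]
            l = seed_len
            while i + l < L and dj + l < len(d_nt) and junction_nt[i + l] == d_nt[dj + l]:
                l += 1
            if l >= min_d_match:
                found = per_d.setdefault(d_id, {})
                if found.get(i, 0) < i + l:
                    found[i] = i + l
    intervals: list[tuple[int, int, str]] = []  # (start, end, d_id)
    for d_id in sorted(per_d):
        found = per_d[d_id]
        for s, e in found.items():
            if not any(s2 <= s and e <= e2 and (s2, e2) != (s, e) for s2, e2 in found.items()):
                intervals.append((s, e, d_id))
    intervals.sort(key=lambda t: (t[2], t[0]))

    # search over tuples; the winning candidate is materialised once at the end
    best_key: tuple | None = None
    best_cand: tuple | None = None  # (v_len, d_id, d_start, d_len, j_len, j_id)

    for v_len in range(vmax + 1):
        for j_len, j_id in j_options:
            if v_len + j_len > L:
                continue
            w_start, w_end = v_len, L - j_len
            # no-D decomposition: one merged N block
            key = (-(v_len + j_len), -v_len, -j_len, (True, "", w_start))
            if best_key is None or key < best_key:
                best_key, best_cand = key, (v_len, None, w_start, 0, j_len, j_id)
            for s, e, d_id in intervals:
                ds = s if s > w_start else w_start
                de = e if e < w_end else w_end
                d_len = de - ds
                if d_len >= min_d_match:
                    key = (-(v_len + d_len + j_len), -v_len, -j_len, (False, d_id, ds))
                    if key < best_key:
                        best_key, best_cand = key, (v_len, d_id, ds, d_len, j_len, j_id)

    assert best_cand is not None
    v_len, d_id, d_start, d_len, j_len, j_id = best_cand
    n1 = d_start - v_len
    n2 = L - j_len - d_start - d_len
    if d_id is None:
        n1, n2 = n1 + n2 + d_len, 0  # single merged N block
    return JunctionDecomposition(v_len, n1, d_id, d_start, d_len, n2, j_len, j_id)


def annotate_clonotypes(
    samples,
    reference: GermlineReference,
    min_d_match: int = 3,
) -> pd.DataFrame:
    """Annotate every clonotype of the given (filtered) samples.

    Returns one row per clonotype with the derived CDR3 features and the
    clonotype's frequency within its sample (computed over the sample's
    post-filter total reads).  Nonproductive clonotypes are retained but
    carry missing amino-acid-level features; AA5-dependent columns are also
    missing for junctions shorter than 7 residues.
    """
    from .statistics import classify_frequency  # local import avoids a cycle

    decomp_cache: dict[str, JunctionDecomposition] = {}
    rows = []
    for sample in samples:
        total = sample.total_reads
        for c in sample.clonotypes:
            dec = decomp_cache.get(c.junction_nt)
            if dec is None:
                dec = decompose_junction(c.junction_nt, reference, min_d_match=min_d_match)
                decomp_cache[c.junction_nt] = dec
            freq = c.read_count / total if total else float("nan")
            row = {
                "sample_id": c.sample_id,
                "donor_id": c.donor_id,
                "replicate_id": c.replicate_id,
                "subset_label": c.subset_label,
                "junction": c.junction_nt,
                "junction_aa": c.junction_aa,
                "v_call": c.v_call,
                "d_call": c.d_call,
                "j_call": c.j_call,
                "read_count": c.read_count,
                "productive": c.productive,
                "cdr3_length": pd.NA,
                "aa5": pd.NA,
                "is_hAA5": pd.NA,
                "inv_t": pd.NA,
                "j_region": pd.NA,
                "n_insertions": dec.total_n,
                "germline_encoded": dec.germline_encoded,
                "frequency": freq,
                "frequency_class": classify_frequency(100.0 * freq) if total else pd.NA,
            }
            if c.productive:
                row["cdr3_length"] = compute_cdr3_length(c.junction_aa)
                aa5 = extract_aa5(c.junction_aa)
                if aa5 is not None:
                    row["aa5"], row["is_hAA5"] = aa5
                    row["inv_t"] = detect_inv_t(c.junction_nt, c.junction_aa)
                if c.j_call:
                    row["j_region"] = j_region_of(c.j_call)
                else:
                    region = classify_j_region_by_suffix(c.junction_aa, reference)
                    row["j_region"] = region if region is not None else pd.NA
            rows.append(row)
    return pd.DataFrame(rows)
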