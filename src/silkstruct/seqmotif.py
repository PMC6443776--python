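"""Tandem-repeat architecture of fibroin-like proteins: polyalanine
block (PAB) detection, PAB+NPAB motif segmentation, NPAB dipeptide /
tripeptide chemistry, and the residue-count → phase-length mapping.

All residue coordinates are 1-based inclusive (protein convention).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

__all__ = [
    "RepeatMotif",
    "SequenceStructureMap",
    "find_polyalanine_blocks",
    "segment_tandem_motifs",
    "classify_npab_chemistry",
    "map_to_phase_lengths",
    "BETA_RESIDUE_RISE_NM",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
INSERT_RESIDUES = set("SVY")

#: axial rise per residue in the extended β conformation (nm)
BETA_RESIDUE_RISE_NM = 0.35


@dataclass
class RepeatMotif:
    """One PAB+NPAB tandem unit; spans are 1-based inclusive."""

    pab_span: tuple
    npab_span: tuple
    insert_span: tuple | None
    motif_length: int

    def as_dict(self):
        return {
            "pab_span": list(self.pab_span),
            "npab_span": list(self.npab_span),
            "insert_span": list(self.insert_span) if self.insert_span else None,
            "motif_length": self.motif_length,
        }


def _validate_sequence(sequence):
    for i, ch in enumerate(sequence):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"invalid amino-acid character {ch!r} at position {i + 1}"
            )


def find_polyalanine_blocks(sequence, min_run=10):
    """Maximal runs of 'A' with length >= min_run, left to right, as
    1-based inclusive (start, end) tuples."""
    _validate_sequence(sequence)
    return [
        (m.start() + 1, m.end())
        for m in re.finditer("A{%d,}" % min_run, sequence)
    ]


def _find_insert(npab_seq, min_len=4, max_len=10, threshold=0.7):
    """Best window of bulky insert residues {S,V,Y} inside an NPAB
    segment: highest fraction wins, longer wins on ties, then leftmost.
    Returns a 0-based (start, end_exclusive) pair or None."""
    n = len(npab_seq)
    is_ins = [ch in INSERT_RESIDUES for ch in npab_seq]
    prefix = [0]
    for flag in is_ins:
        prefix.append(prefix[-1] + flag)
    best = None  # (fraction, length, -start)
    best_span = None
    for length in range(min_len, max_len + 1):
        for start in range(0, n - length + 1):
            frac = (prefix[start + length] - prefix[start]) / length
            if frac < threshold:
                continue
            key = (frac, length, -start)
            if best is None or key > best:
                best = key
                best_span = (start, start + length)
    return best_span


def segment_tandem_motifs(sequence, pab_blocks, insert_threshold=0.7):
    """Split the sequence into tandem repeat motifs, each spanning from
    one PAB start to the next PAB start.

    The trailing PAB begins an incomplete unit and is not returned as a
    motif.  Within each NPAB the short non-repeated insert is located as
    the best {S,V,Y}-rich window of length 4–10 (see ``_find_insert``).
    """
    if len(pab_blocks) < 2:
        warnings.warn("fewer than two polyalanine blocks; no complete motifs")
        return []
    motifs = []
    for (s0, e0), (s1, _) in zip(pab_blocks, pab_blocks[1:]):
        npab_start, npab_end = e0 + 1, s1 - 1
        if npab_end < npab_start:
            raise ValueError("adjacent polyalanine blocks with empty NPAB")
        npab_seq = sequence[npab_start - 1:npab_end]
        ins = _find_insert(npab_seq, threshold=insert_threshold)
        insert_span = None
        if ins is not None:
            insert_span = (npab_start + ins[0], npab_start + ins[1] - 1)
        motifs.append(RepeatMotif(
            pab_span=(s0, e0),
            npab_span=(npab_start, npab_end),
            insert_span=insert_span,
            motif_length=s1 - s0,
        ))
    return motifs


def classify_npab_chemistry(motif: RepeatMotif, sequence):
    """Greedy left-to-right tiling of the NPAB into Gly-Gly-X and Gly-X
    tiles (longer tile preferred on ties), plus the Gly+Ala molar
    fraction of the whole sequence."""
    s0, e0 = motif.npab_span
    seg = sequence[s0 - 1:e0]
    n = len(seg)
    counts = {"ggx": 0, "gx": 0, "untiled": 0}
    i = 0
    while i < n:
        if seg[i] == "G" and i + 2 < n and seg[i + 1] == "G":
            counts["ggx"] += 3
            i += 3
        elif seg[i] == "G" and i + 1 < n:
            counts["gx"] += 2
            i += 2
        else:
            counts["untiled"] += 1
            i += 1
    gly_ala = sum(1 for ch in sequence if ch in "GA") / len(sequence)
    return {
        "npab_length": n,
        "gx_fraction": counts["gx"] / n if n else 0.0,
        "ggx_fraction": counts["ggx"] / n if n else 0.0,
        "untiled_fraction": counts["untiled"] / n if n else 0.0,
        "gly_ala_fraction_sequence": gly_ala,
    }


def _round_half_up(x, ndigits=0):
    scale = 10.0 ** ndigits
    import math

    return math.floor(x * scale + 0.5) / scale


@dataclass
class SequenceStructureMap:
    """Residue counts mapped to predicted phase lengths."""

    n_crystal_residues: int
    n_amorphous_residues: int
    residue_rise: float            # nm per residue
    crystal_length: float          # nm (rounded to 0.1 for display)
    crystal_length_exact: float    # nm
    amorphous_contour: float       # nm
    amorphous_shrinkage: float | None  # percent, vs target phase thickness
    predicted_long_period: float | None  # nm


def map_to_phase_lengths(pab_residues, npab_crystal_residues,
                         amorphous_residues,
                         residue_rise=BETA_RESIDUE_RISE_NM,
                         amorphous_phase_thickness=None) -> SequenceStructureMap:
    """Map motif residue counts to predicted phase lengths.

    The crystal-forming segment is PAB plus the NPAB stretch up to the
    insert; its β-sheet length is (counts × rise).  The remaining NPAB
    residues form the amorphous contour, whose percent shrinkage down to
    a supplied amorphous phase thickness is reported when that thickness
    is given and the contour is nonzero.
    """
    if pab_residues < 0 or npab_crystal_residues < 0 or amorphous_residues < 0:
        raise ValueError("residue counts must be non-negative")
    n_cry = pab_residues + npab_crystal_residues
    crystal_exact = n_cry * residue_rise
    contour = amorphous_residues * residue_rise
    shrinkage = None
    if amorphous_phase_thickness is not None and contour > 0:
        shrinkage = (contour - amorphous_phase_thickness) / contour * 100.0
    predicted_lp = None
    if amorphous_phase_thickness is not None:
        predicted_lp = crystal_exact + amorphous_phase_thickness
    return SequenceStructureMap(
        n_crystal_residues=n_cry,
        n_amorphous_residues=amorphous_residues,
        residue_rise=residue_rise,
        crystal_length=_round_half_up(crystal_exact, 1),
        crystal_length_exact=crystal_exact,
        amorphous_contour=contour,
        amorphous_shrinkage=shrinkage,
        predicted_long_period=predicted_lp,
    )
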