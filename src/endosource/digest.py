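"""In-silico TRFLP: degenerate-primer matching, virtual digestion, matching.

Given a 16S rDNA sequence, the amplicon delimited by the degenerate
primer pair 799f (6FAM-labelled forward, ``AACMGGATTAGATACCCKG``) and
1492rh (Max550-labelled reverse, ``HGGHTACCTTGTTACGACTT``) is extracted
and virtually restricted with DdeI (recognition CTNAG, cutting one
nucleotide into the site: C^TNAG).  The labelled terminal fragments are
the forward fragment (amplicon 5' end to the first top-strand cut) and
the reverse fragment (the same measured from the 5' end of the
reverse-complement strand); primers are included in the lengths.
Predicted fragments are then matched against observed profile
categories within a size tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

#: IUPAC nucleotide codes accepted in sequences and primers
IUPAC_SETS: dict[str, frozenset] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}


class PrimerMatchError(ValueError):
    """Raised when a primer fails to match a sequence."""


def _validate_iupac(seq: str, what: str = "sequence") -> None:
    for i, base in enumerate(seq.upper()):
        if base not in IUPAC_SETS:
            raise ValueError(
                f"invalid IUPAC symbol {base!r} at position {i} in {what}"
            )


@dataclass(frozen=True)
class PrimerSpec:
    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    label: str = "none"  # "6FAM" | "Max550" | "none"

    def __post_init__(self):
        _validate_iupac(self.sequence, what=f"primer {self.name}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")


PRIMER_799F = PrimerSpec("799f", "AACMGGATTAGATACCCKG", "forward", "6FAM")
PRIMER_1492RH = PrimerSpec("1492rh", "HGGHTACCTTGTTACGACTT", "reverse", "Max550")


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme as recognition string plus cut offset.

    ``cut_offset`` is the number of nucleotides into the site, on the
    labelled strand, at which the backbone is cut (DdeI: C^TNAG -> 1).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        _validate_iupac(self.recognition, what=f"enzyme {self.name} recognition")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition site")


DDEI = Enzyme("DdeI", "CTNAG", 1)


@dataclass(frozen=True)
class DigestPrediction:
    """Predicted labelled terminal fragments of one amplicon."""

    sequence_id: str
    enzyme: str
    fwd_fragment: int  # 6FAM channel, bp
    rev_fragment: int  # Max550 channel, bp
    n_sites: int


def match_degenerate(sequence: str, primer: str | PrimerSpec) -> list[int]:
    """0-based positions where a degenerate primer matches exactly.

    A primer base matches a sequence base when the primer's IUPAC set
    contains that base (no indels, no mismatches).  Callers matching a
    reverse-orientation primer should pass the reverse complement of
    the sequence (see :func:`extract_amplicon`).
    """
    pseq = (primer.sequence if isinstance(primer, PrimerSpec) else primer).upper()
    seq = sequence.upper()
    _validate_iupac(pseq, what="primer")
    _validate_iupac(seq, what="sequence")
    if len(pseq) > len(seq):
        return []
    sets = [IUPAC_SETS[b] for b in pseq]
    return [
        i
        for i in range(len(seq) - len(pseq) + 1)
        if all(seq[i + j] in sets[j] for j in range(len(pseq)))
    ]


def extract_amplicon(
    sequence: str,
    fwd: PrimerSpec = PRIMER_799F,
    rev: PrimerSpec = PRIMER_1492RH,
) -> str:
    """Extract the amplicon spanned by a primer pair, primers included.

    The amplicon runs from the 5' end of the leftmost forward-primer
    match to the 3' end of the outermost reverse-primer match (the pair
    maximizing product length, as amplification favours).
    """
    seq = sequence.upper()
    fwd_pos = match_degenerate(seq, fwd)
    if not fwd_pos:
        raise PrimerMatchError(f"forward primer {fwd.name} not found")
    rc = reverse_complement(seq)
    rev_pos = match_degenerate(rc, rev)
    if not rev_pos:
        raise PrimerMatchError(f"reverse primer {rev.name} not found")
    start = min(fwd_pos)
    end = len(seq) - min(rev_pos)  # 3' end (exclusive) on the forward strand
    if end <= start:
        raise PrimerMatchError(
            f"primers {fwd.name}/{rev.name} match in the wrong orientation order"
        )
    return seq[start:end]


def _find_sites(strand: str, recognition: str) -> list[int]:
    """0-based start positions of recognition sites on one strand.

    Ambiguity codes inside the scanned strand count as a site only if
    every expansion of the strand base is accepted by the recognition
    pattern (conservative: no phantom cut sites from N runs).
    """
    pat = [IUPAC_SETS[b] for b in recognition.upper()]
    s = strand.upper()
    hits = []
    for i in range(len(s) - len(pat) + 1):
        if all(IUPAC_SETS[s[i + j]] <= pat[j] for j in range(len(pat))):
            hits.append(i)
    return hits


def predict_terminal_fragments(
    amplicon: str, enzyme: Enzyme = DDEI, sequence_id: str = ""
) -> DigestPrediction:
    """Predict the labelled terminal fragment lengths of an amplicon.

    The forward (6FAM) fragment is the distance from the amplicon 5' end
    to the first cut on the top strand; the reverse (Max550) fragment is
    the same computed on the reverse complement.  With no recognition
    site, both fragments equal the amplicon length.
    """
    seq = amplicon.upper()
    _validate_iupac(seq, what="amplicon")
    top = _find_sites(seq, enzyme.recognition)
    rc = reverse_complement(seq)
    bottom = _find_sites(rc, enzyme.recognition)
    fwd = top[0] + enzyme.cut_offset if top else len(seq)
    rev = bottom[0] + enzyme.cut_offset if bottom else len(seq)
    return DigestPrediction(
        sequence_id=sequence_id,
        enzyme=enzyme.name,
        fwd_fragment=int(fwd),
        rev_fragment=int(rev),
        n_sites=len(top),
    )


def digest_fragments(amplicon: str, enzyme: Enzyme = DDEI) -> list[int]:
    """All top-strand fragment lengths of a complete digest (bookkeeping).

    The lengths sum to the amplicon length; the first element is the
    forward terminal fragment.
    """
    seq = amplicon.upper()
    cuts = [p + enzyme.cut_offset for p in _find_sites(seq, enzyme.recognition)]
    bounds = [0] + cuts + [len(seq)]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]


def read_sequences(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    for rid, seq in records:
        _validate_iupac(seq, what=f"record {rid}")
    return records


def predict_for_sequences(
    records: Iterable[tuple[str, str]],
    fwd: PrimerSpec = PRIMER_799F,
    rev: PrimerSpec = PRIMER_1492RH,
    enzyme: Enzyme = DDEI,
) -> tuple[list[DigestPrediction], list[tuple[str, str]]]:
    """Digest predictions for many sequences.

    Returns (predictions, failures); failures are (id, reason) for
    records where a primer did not match.
    """
    predictions, failures = [], []
    for rid, seq in records:
        try:
            amplicon = extract_amplicon(seq, fwd, rev)
        except PrimerMatchError as exc:
            failures.append((rid, str(exc)))
            continue
        predictions.append(predict_terminal_fragments(amplicon, enzyme, sequence_id=rid))
    return predictions, failures


def predictions_to_frame(predictions: Sequence[DigestPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"id": p.sequence_id, "fwd_bp": p.fwd_fragment,
             "rev_bp": p.rev_fragment, "n_sites": p.n_sites}
            for p in predictions
        ],
        columns=["id", "fwd_bp", "rev_bp", "n_sites"],
    )


def match_predictions_to_profile(
    predictions: Sequence[DigestPrediction],
    present_categories: Iterable[tuple[str, int]],
    tolerance: int = 1,
) -> dict[tuple[str, int], list[str]]:
    """Match predictions to present (dye, size) categories.

    A prediction matches a category when ``|predicted - category| <=
    tolerance`` on the corresponding dye channel (forward fragment vs
    6FAM, reverse vs Max550).  All matches are reported; several
    sequences may match one category and vice versa.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    cats = sorted(set(present_categories))
    out: dict[tuple[str, int], list[str]] = {}
    for dye, size in cats:
        hits = []
        for p in predictions:
            predicted = p.fwd_fragment if dye == "6FAM" else p.rev_fragment
            if abs(predicted - size) <= tolerance:
                hits.append(p.sequence_id)
        if hits:
            out[(dye, size)] = hits
    return out


def exclusions_from_predictions(
    predictions: Sequence[DigestPrediction], tolerance: int = 0
) -> list[tuple[str, tuple[int, int]]]:
    """Exclusion ranges covering predicted organellar fragments.

    Used to strip chloroplast 16S / mitochondrial 18S categories from
    peak tables via :func:`endosource.peaks.remove_excluded_sizes`.
    """
    out = []
    for p in predictions:
        out.append(("6FAM", (p.fwd_fragment - tolerance, p.fwd_fragment + tolerance)))
        out.append(("Max550", (p.rev_fragment - tolerance, p.rev_fragment + tolerance)))
    return out
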