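"""Nick-site arithmetic for engineered ssDNA-gap substrates.

A Cas9 D10A nickase guided by a crRNA cuts exactly one strand — the strand
that base-pairs with the guide — 3 nt 5' of the NGG PAM.  Two nicks on the
same strand define an excisable single-stranded gap; this module locates the
protospacers on a reference genome and measures the gap in nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["NickSite", "read_fasta", "lambda_genome", "find_nick_site", "gap_length_nt"]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NickSite:
    """A single-strand cut located on the reference top-strand coordinate.

    ``position`` is the 0-based inter-nucleotide coordinate of the cut: the
    phosphodiester bond between reference positions ``position - 1`` and
    ``position`` on the nicked strand.
    """

    position: int
    strand: str  # strand carrying the protospacer ('+' or '-')
    protospacer_start: int
    spacer: str
    pam: str


def read_fasta(path: str | Path) -> str:
    """Single-record FASTA reader returning the uppercased sequence."""
    seq_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if seq_parts:
                    break  # only the first record
                continue
            seq_parts.append(line.strip())
    if not seq_parts:
        raise ValueError(f"no sequence found in {path}")
    return "".join(seq_parts).upper()


def lambda_genome() -> str:
    """The 48,502-bp Enterobacteria phage lambda reference sequence."""
    ref = resources.files("kymotrace.data").joinpath("lambda_phage.fasta")
    with resources.as_file(ref) as path:
        return read_fasta(path)


def _pam_ok(pam: str) -> bool:
    return len(pam) == 3 and pam[1:] == "GG"


def _find_exact(genome: str, spacer: str) -> NickSite | None:
    n = len(spacer)
    # protospacer on top strand: PAM immediately 3' on the same strand;
    # the guide pairs with the bottom strand, which is nicked between
    # protospacer positions n-4 and n-3 (3 nt 5' of the PAM).  The cut
    # coordinate is the same on both strands (blunt-site geometry).
    start = genome.find(spacer)
    while start != -1:
        pam = genome[start + n : start + n + 3]
        if _pam_ok(pam):
            return NickSite(
                position=start + n - 3,
                strand="+",
                protospacer_start=start,
                spacer=spacer,
                pam=pam,
            )
        start = genome.find(spacer, start + 1)
    # protospacer on bottom strand: appears as revcomp on top; PAM lies
    # 5' of the match in top coordinates, read on the bottom strand.
    rc = _revcomp(spacer)
    start = genome.find(rc)
    while start != -1:
        pam = _revcomp(genome[start - 3 : start])
        if start >= 3 and _pam_ok(pam):
            return NickSite(
                position=start + 3,
                strand="-",
                protospacer_start=start,
                spacer=spacer,
                pam=pam,
            )
        start = genome.find(rc, start + 1)
    return None


def find_nick_site(genome: str, spacer: str, min_spacer_len: int = 18) -> NickSite:
    """Locate the D10A nick programmed by ``spacer`` (DNA alphabet).

    crRNA sequences are often printed with trailing scaffold bases attached
    to the 20-nt spacer; if the full sequence has no PAM-adjacent match the
    3' end is trimmed one base at a time down to ``min_spacer_len``.
    """
    spacer = spacer.upper().replace("U", "T")
    for end in range(len(spacer), min_spacer_len - 1, -1):
        hit = _find_exact(genome, spacer[:end])
        if hit is not None:
            return hit
    raise ValueError(f"no PAM-adjacent protospacer found for {spacer!r}")


def gap_length_nt(genome: str, spacer_a: str, spacer_b: str) -> int:
    """Nucleotides of nicked strand between two same-strand D10A nick sites."""
    a = find_nick_site(genome, spacer_a)
    b = find_nick_site(genome, spacer_b)
    return abs(b.position - a.position)
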