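"""Independent brute-force oracles used by the tests.

These walk transcript structures base by base and never call the
coordinate arithmetic they are checking.
"""

from fusiontriage.annotation import Transcript


def exonic_positions(tx: Transcript) -> list[int]:
    """Every exonic genomic position, in transcription (5'→3') order."""
    out: list[int] = []
    for ex in tx.exons:
        if tx.gene.strand == "+":
            out.extend(range(ex.g_start, ex.g_end + 1))
        else:
            out.extend(range(ex.g_end, ex.g_start - 1, -1))
    return out


def coding_position_set(tx: Transcript) -> set[int]:
    cds: set[int] = set()
    for s, e in tx.cds_segments:
        cds.update(range(s, e + 1))
    return cds


def brute_force_offset(tx: Transcript, gpos: int, side: str) -> int:
    """Coding-nt count by literal enumeration over every transcript base.

    five_prime: coding bases at-or-upstream of gpos (inclusive);
    three_prime: coding bases strictly upstream of gpos.
    """
    order = exonic_positions(tx)
    coding = coding_position_set(tx)
    idx = order.index(gpos)
    upto = idx + 1 if side == "five_prime" else idx
    return sum(1 for p in order[:upto] if p in coding)


def codon_walk_in_frame(tx5: Transcript, pos5: int, tx3: Transcript, pos3: int) -> bool:
    """Frame oracle: walk both partners' coding bases one by one.

    The chimera is in-frame iff the codon phase reached at the end of
    the retained 5' segment equals the native codon phase of the first
    retained 3' base.
    """
    n5 = brute_force_offset(tx5, pos5, "five_prime")
    n3_excluded = brute_force_offset(tx3, pos3, "three_prime")
    return n5 % 3 == n3_excluded % 3
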