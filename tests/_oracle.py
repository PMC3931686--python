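"""Independent exhaustive local-alignment oracle for aligner tests.

Uses biotite's optimal alignment (full dynamic-programming matrix) with
the same scoring as the production kernel (match +1, mismatch -1,
linear gap -2), on both strands. Kept deliberately separate from the
package's own alignment code path.
"""

from __future__ import annotations

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

_MATRIX = balign.SubstitutionMatrix(
    bseq.NucleotideSequence.alphabet_unamb,
    bseq.NucleotideSequence.alphabet_unamb,
    np.where(np.eye(4, dtype=bool), 1, -1).astype(np.int32))

_RC = str.maketrans("ACGT", "TGCA")


def _one_strand(query: str, subject: str):
    q = bseq.NucleotideSequence(query)
    s = bseq.NucleotideSequence(subject)
    aln = balign.align_optimal(q, s, _MATRIX, gap_penalty=-2, local=True,
                               max_number=1)[0]
    trace = aln.trace
    both = (trace[:, 0] != -1) & (trace[:, 1] != -1)
    qa = np.asarray(q.code)
    sa = np.asarray(s.code)
    matches = int(np.sum(qa[trace[both, 0]] == sa[trace[both, 1]]))
    columns = len(trace)
    q_res = int(np.sum(trace[:, 0] != -1))
    return aln.score, matches, columns, q_res


def oracle_best_local(fragment: str, subject: str):
    """Best local alignment over both strands.

    Returns (score, identity_pct, coverage) with identity =
    matches / alignment columns and coverage = aligned query residues /
    fragment length.
    """
    best = None
    for q in (fragment, fragment.translate(_RC)[::-1]):
        score, matches, columns, q_res = _one_strand(q, subject)
        if best is None or score > best[0]:
            best = (score, matches, columns, q_res)
    score, matches, columns, q_res = best
    if columns == 0:
        return 0, 0.0, 0.0
    return score, 100.0 * matches / columns, q_res / len(fragment)
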