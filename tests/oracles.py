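"""Independent oracles shared by the test suite (kept separate from the
implementation paths they check)."""

import itertools
import re

from mitocr import cr_annotation as cra


def expansions(pattern):
    """All fixed-gap expansions of a motif pattern as compiled regexes, in
    the order the scanner explores them (gap lengths ascending, leftmost gap
    outermost)."""
    ranges = []
    for e in pattern.elements:
        if isinstance(e, cra.Gap):
            ranges.append([(e, g) for g in range(e.min_len, e.max_len + 1)])
        else:
            ranges.append([(e, None)])
    out = []
    for combo in itertools.product(*ranges):
        parts = []
        for e, g in combo:
            if isinstance(e, cra.Literal):
                parts.append(re.escape(e.seq))
            elif isinstance(e, cra.Alternation):
                parts.append("(?:" + "|".join(map(re.escape, e.options)) + ")")
            else:
                parts.append("[ACGTN]{%d}" % g)
        out.append(re.compile("".join(parts)))
    return out


def brute_force_scan(seq, pattern):
    """All (start, end) motif hits by trying every start position against
    every gap expansion via the regex engine."""
    regexes = expansions(pattern)
    hits = []
    for pos in range(len(seq)):
        for rx in regexes:
            m = rx.match(seq, pos)
            if m:
                hits.append((pos + 1, m.end()))
                break
    return hits
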