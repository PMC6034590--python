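"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own location machinery: the
location walker below interprets the grammar one base position at a
time, so agreement with the package's substring-based resolver is a
meaningful check.
"""

import re

_COMP = {"a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}

_SPAN = re.compile(r"^<?(\d+)(?:\.\.>?(\d+))?$")


def _split_top(text: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def walk_positions(text: str) -> list[tuple[int, str]]:
    """Per-base (position, strand) list for a location string."""
    text = text.strip()
    if text.startswith("complement(") and text.endswith(")"):
        inner = walk_positions(text[len("complement(") : -1])
        return [(p, "-" if s == "+" else "+") for p, s in reversed(inner)]
    for op in ("join(", "order("):
        if text.startswith(op) and text.endswith(")"):
            out: list[tuple[int, str]] = []
            for part in _split_top(text[len(op) : -1]):
                out.extend(walk_positions(part))
            return out
    m = _SPAN.match(text)
    assert m, f"oracle cannot walk {text!r}"
    a = int(m.group(1))
    b = int(m.group(2)) if m.group(2) else a
    return [(p, "+") for p in range(a, b + 1)]


def resolve_per_base(location_text: str, sequence: str) -> str:
    """Resolve a location by fetching one base at a time."""
    out = []
    for pos, strand in walk_positions(location_text):
        base = sequence[pos - 1].lower()
        out.append(base if strand == "+" else _COMP[base])
    return "".join(out)
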