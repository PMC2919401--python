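"""Substring-presence index over a reference set.

The index answers "is this word a substring of the reference (per
strand mode)?" exactly, in time proportional to the word length, via a
suffix automaton built over the N-free segments of the reference joined
with a separator character.  Because queries are restricted to
``{A,C,G,T}`` they can never cross a separator, so presence in the
joined text is equivalent to presence within a single segment.

The automaton is built lazily on the first membership query; batch
consumers (MAW enumeration, the mappability filter) work directly from
the reference segments with vectorised k-mer machinery and never touch
it.
"""

from __future__ import annotations

from .reference import DNA_ALPHABET, BOTH_STRANDS, ReferenceSet

_SEPARATOR = "#"


class SuffixAutomaton:
    """Classic online suffix automaton (DAWG) over an arbitrary text.

    States are stored in parallel lists; transitions are per-state
    dicts.  ``accepts(w)`` is True iff ``w`` is a substring of the text.
    """

    __slots__ = ("_next", "_link", "_len", "_last")

    def __init__(self, text: str = "") -> None:
        self._next: list[dict[str, int]] = [{}]
        self._link: list[int] = [-1]
        self._len: list[int] = [0]
        self._last = 0
        for ch in text:
            self.extend(ch)

    def extend(self, ch: str) -> None:
        nxt, link, lens = self._next, self._link, self._len
        cur = len(nxt)
        nxt.append({})
        link.append(-1)
        lens.append(lens[self._last] + 1)
        p = self._last
        while p != -1 and ch not in nxt[p]:
            nxt[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nxt[p][ch]
            if lens[p] + 1 == lens[q]:
                link[cur] = q
            else:
                clone = len(nxt)
                nxt.append(dict(nxt[q]))
                link.append(link[q])
                lens.append(lens[p] + 1)
                while p != -1 and nxt[p].get(ch) == q:
                    nxt[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        self._last = cur

    def accepts(self, word: str) -> bool:
        state = 0
        nxt = self._next
        for ch in word:
            trans = nxt[state].get(ch)
            if trans is None:
                return False
            state = trans
        return True

    def __len__(self) -> int:
        return len(self._next)


class SubstringIndex:
    """Queryable presence structure over a :class:`ReferenceSet`.

    Attributes
    ----------
    source:
        The indexed reference set.
    strand_mode:
        Inherited from the reference; ``"both"`` means presence on
        either strand.
    """

    def __init__(self, source: ReferenceSet) -> None:
        self.source = source
        self.strand_mode = source.strand_mode
        self.segments: list[str] = source.clean_segments()
        self._automaton: SuffixAutomaton | None = None
        # caches attached by other modules (mappability seed indexes)
        self._mappability_cache: dict = {}

    @property
    def automaton(self) -> SuffixAutomaton:
        if self._automaton is None:
            self._automaton = SuffixAutomaton(_SEPARATOR.join(self.segments))
        return self._automaton

    def has_substring(self, word: str) -> bool:
        """True iff ``word`` occurs in the indexed text per strand mode."""
        if not word:
            raise ValueError("query word must be non-empty")
        bad = set(word) - set(DNA_ALPHABET)
        if bad:
            raise ValueError(
                f"query word contains characters outside {{A,C,G,T}}: {sorted(bad)}"
            )
        return self.automaton.accepts(word)

    def __contains__(self, word: str) -> bool:
        return self.has_substring(word)


def build_index(ref: ReferenceSet) -> SubstringIndex:
    """Build a substring-presence index over ``ref``.

    Validation of the reference (non-empty, legal characters) happens in
    :class:`ReferenceSet` itself; this constructor only wires it to the
    query structure.
    """
    return SubstringIndex(ref)


def has_substring(index: SubstringIndex, word: str) -> bool:
    """Functional alias for :meth:`SubstringIndex.has_substring`."""
    return index.has_substring(word)
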