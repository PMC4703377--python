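"""Bundled English function-word stop list (~150 entries).

Seeded from determiners, prepositions, conjunctions, pronouns and auxiliary
verbs; user-overridable via ``load_stopwords``. Content words never appear
here — the list exists to keep context vectors on "meaningful" units.
"""

from pathlib import Path

DEFAULT_STOPWORDS = frozenset("""
a about above after again against all also although am among amongst an and
any are as at be because been before being below beside besides between both
but by can cannot could did do does doing down during each either enough etc
few for from further had has have having he her here hers herself him himself
his how however i if in into is it its itself just least less many may me
might mine more most much must my myself neither no nor not nothing now of
off often on once only onto or other our ours ourselves out over own per
rather same shall she should since so some somewhat still such than that the
their theirs them themselves then there therefore these they this those
though through throughout thus to too under until unto up upon us very was we
were what when whence where whereas whether which while whilst who whom whose
why will with within without would yet you your yours yourself yourselves
""".split())


def load_stopwords(path) -> frozenset[str]:
    """Read a stop list: one term per line, UTF-8, blank lines ignored."""
    return frozenset(
        line.strip().lower()
        for line in Path(path).read_text("utf-8").splitlines()
        if line.strip()
    )
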