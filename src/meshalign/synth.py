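"""Seeded synthetic sequence families for tests and demos.

Families are generated the way progressive alignment assumes they arose: a
random ancestor mutated independently along each lineage by point
substitutions and short indels.  Everything is driven by a
``numpy.random.Generator``, so a family is regenerable bit-exactly from its
seed.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

__all__ = ["random_sequence", "synth_family"]


def random_sequence(n: int, rng: np.random.Generator, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def synth_family(
    m: int,
    n: int,
    mutation_rate: float = 0.1,
    indel_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
    alphabet: str = "ACGT",
):
    """``m`` descendants of one random length-``n`` ancestor.

    Each descendant applies, per ancestor position, a substitution with
    probability ``mutation_rate`` (to a uniformly chosen different symbol)
    and an indel with probability ``indel_rate`` (deletion or single-symbol
    insertion, equiprobable).  Rate 0 yields ``m`` identical copies.

    Returns ``(sequences, ancestor)``.
    """
    for rate in (mutation_rate, indel_rate):
        if not 0 <= rate <= 1:
            raise InputError("rates must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = list(alphabet)
    ancestor = random_sequence(n, rng, alphabet)
    seqs = []
    for _ in range(m):
        out = []
        for ch in ancestor:
            if rng.random() < mutation_rate:
                others = [c for c in letters if c != ch]
                ch = letters[0] if not others else others[int(rng.integers(len(others)))]
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                out.append(ch)
                out.append(letters[int(rng.integers(len(letters)))])
            else:
                out.append(ch)
        if not out:  # keep sequences non-empty
            out.append(letters[int(rng.integers(len(letters)))])
        seqs.append("".join(out))
    return seqs, ancestor
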