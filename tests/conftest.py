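import itertools
from pathlib import Path

import numpy as np
import pytest

from rrtzf.io import SequenceRecord
from rrtzf.motif_grammar import Anchor, MotifPattern, Spacer, load_grammars
from rrtzf.synth import CLASS_NAMES, ProteomeSpec, generate_proteome

DATA = Path(__file__).parent / "data"

#: the conserved RR-region peptide used as the family search query
QUERY_PEPTIDE = "IDAYSCDHFRMYDFKVRRCARGRSHDWTECPYAH"


@pytest.fixture(scope="session")
def grammars():
    return load_grammars()


@pytest.fixture(scope="session")
def query_record():
    return SequenceRecord("AtTZF3_query", QUERY_PEPTIDE)


@pytest.fixture(scope="session")
def small_proteome():
    """5 proteins per architecture class, fixed seed."""
    spec = ProteomeSpec(counts={c: 5 for c in CLASS_NAMES}, seed=11)
    return generate_proteome(spec)


@pytest.fixture
def data_dir():
    return DATA


def brute_force_scan(seq: str, pattern: MotifPattern):
    """Independent oracle: enumerate all anchor index tuples satisfying the
    spacer bounds by filtering position combinations, without walking
    spacers.  Exponential — use on short sequences / sparse anchors only.
    """
    elements = pattern.elements
    anchors = [e for e in elements if isinstance(e, Anchor)]
    # gap bounds between consecutive anchors
    gaps = []
    cur = None
    for e in elements:
        if isinstance(e, Anchor):
            if cur is not None:
                gaps.append(cur)
            cur = (0, 0)
        else:
            cur = (cur[0] + e.min, cur[1] + e.max) if cur != (0, 0) else (e.min, e.max)
    positions = [
        [i for i, c in enumerate(seq) if c in a.residues] for a in anchors
    ]

    def rec(idx, prev, acc):
        if idx == len(anchors):
            yield tuple(acc)
            return
        for p in positions[idx]:
            if prev is None:
                ok = True
            else:
                gap = p - prev - 1
                lo, hi = gaps[idx - 1]
                ok = lo <= gap <= hi
            if ok and (prev is None or p > prev):
                acc.append(p)
                yield from rec(idx + 1, p, acc)
                acc.pop()

    out = set()
    for combo in rec(0, None, []):
        out.add(tuple((seq[p], p + 1) for p in combo))
    return out


def random_protein(rng: np.random.Generator, length: int,
                   alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
                   boost: str = "CH", boost_factor: float = 4.0) -> str:
    """Random protein with elevated anchor-residue frequency so short
    grammar hits actually occur."""
    w = np.array([boost_factor if a in boost else 1.0 for a in alphabet])
    w = w / w.sum()
    return "".join(rng.choice(list(alphabet), size=length, p=w))
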