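import numpy as np
import pandas as pd
import pytest

from whorlherit.pedigree import Pedigree, PedigreeRecord


@pytest.fixture
def trio():
    """Sire A, dam B, offspring C."""
    return Pedigree([
        PedigreeRecord("A", None, None, "M"),
        PedigreeRecord("B", None, None, "F"),
        PedigreeRecord("C", "A", "B", "M"),
    ])


@pytest.fixture
def fullsib_pedigree():
    """Two founders, two full sibs, plus an offspring of a full-sib mating."""
    return Pedigree([
        PedigreeRecord("A", None, None, "M"),
        PedigreeRecord("B", None, None, "F"),
        PedigreeRecord("C", "A", "B", "M"),
        PedigreeRecord("D", "A", "B", "F"),
        PedigreeRecord("E", "C", "D", "M"),
    ])


def random_pedigree(n: int, seed: int, p_founder: float = 0.3) -> Pedigree:
    """Random valid pedigree: each non-founder picks earlier parents."""
    rng = np.random.default_rng(seed)
    records = [PedigreeRecord("I0", None, None, "M"), PedigreeRecord("I1", None, None, "F")]
    for i in range(2, n):
        if rng.random() < p_founder:
            records.append(PedigreeRecord(f"I{i}", None, None, "M" if i % 2 else "F"))
            continue
        sire = f"I{rng.integers(0, i)}"
        dam = f"I{rng.integers(0, i)}"
        if sire == dam:
            dam = None
        # one parent may be unknown
        if rng.random() < 0.2:
            sire = None
        records.append(PedigreeRecord(f"I{i}", sire, dam, "M" if i % 2 else "F"))
    return Pedigree(records)


def halfsib_phenotypes(n_sires: int, offspring: int, seed: int, n_cat: int = 2):
    """Pedigree + phenotype frame with random categories, for filter tests."""
    from whorlherit.phenotypes import TraitDataset

    rng = np.random.default_rng(seed)
    records, rows = [], []
    for j in range(n_sires):
        s = f"S{j}"
        records.append(PedigreeRecord(s, None, None, "M"))
        for m in range(offspring):
            o = f"O{j}_{m}"
            records.append(PedigreeRecord(o, s, None, "M" if m % 2 else "F"))
            rows.append((o, "M" if m % 2 else "F", int(rng.integers(1, n_cat + 1))))
    ped = Pedigree(records)
    data = TraitDataset("whorl_number", pd.DataFrame(rows, columns=["id", "sex", "category"]))
    return ped, data
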