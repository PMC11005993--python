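import math

import numpy as np
import pytest

from promdpp import builtin_tables, default_element_definitions
from promdpp.dpp_tables import StepParamTable


@pytest.fixture(scope="session")
def tables():
    return builtin_tables()


@pytest.fixture(scope="session")
def defs():
    return default_element_definitions()


@pytest.fixture(scope="session")
def toy_k2_table():
    """Dinucleotide table with AA=1.0, AC=2.0 and 0 elsewhere."""
    values = {a + b: 0.0 for a in "ACGT" for b in "ACGT"}
    values["AA"] = 1.0
    values["AC"] = 2.0
    return StepParamTable(property_name="toy", step_size=2, units="au", values=values)


def naive_chain(seq: str, table: StepParamTable) -> list[float]:
    """Independent brute-force oracle: sliding-window dict lookup."""
    seq = seq.upper()
    k = table.step_size
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if all(b in "ACGT" for b in kmer):
            out.append(table.values[kmer])
        else:
            out.append(math.nan)
    return out


def naive_mean_sd(columns: dict[int, list[float]]):
    """Two-pass mean / sample SD per position over non-missing values."""
    out = {}
    for pos, vals in columns.items():
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            continue
        n = len(vals)
        mean = sum(vals) / n
        if n >= 2:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        else:
            sd = math.nan
        out[pos] = (mean, sd, n)
    return out


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))
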