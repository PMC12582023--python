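import numpy as np
import pandas as pd
import pytest

from splicecov.design import SampleSheet, encode


def write_sam(path, reads, chroms=(("chr1", 100_000),)):
    """Write a minimal SAM text file.

    ``reads`` is a list of dicts with keys: name, chrom, pos (1-based),
    cigar, and optional flag, xs (strand tag).
    """
    qlen = {"M": True, "I": True, "S": True, "=": True, "X": True}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, ln in chroms:
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for r in reads:
            # sequence length must match the query-consuming CIGAR length
            import re

            n = sum(
                int(num) for num, op in re.findall(r"(\d+)([MIDNSHP=X])", r["cigar"])
                if op in qlen
            )
            fields = [
                r.get("name", "r"), str(r.get("flag", 0)), r["chrom"],
                str(r["pos"]), "60", r["cigar"], "*", "0", "0",
                "A" * max(n, 1), "*",
            ]
            if "xs" in r:
                fields.append(f"XS:A:{r['xs']}")
            fh.write("\t".join(fields) + "\n")
    return path


@pytest.fixture
def two_condition_sheet():
    """10 + 10 samples, balanced sex within condition."""
    rows = []
    for k, cond in enumerate(("control", "disease")):
        for i in range(10):
            rows.append({
                "sample_id": f"s{k}{i}", "condition": cond,
                "sex": "M" if i % 2 else "F", "age": 20 + 3 * i,
            })
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def two_condition_design(two_condition_sheet):
    return encode(two_condition_sheet, ["sex", "age"])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
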