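"""Packaged paired NGS-vs-karyotype fixture (44 numbered rows + aggregate).

The fixture transcribes, verbatim, the published side-by-side comparison of
cfDNA NGS copy-number shorthand and conventional bone-marrow cytogenetic
reports for 89 myeloid samples: 44 individually listed pairs plus one
aggregate row standing for 45 samples with a normal karyotype on both sides.
Typography is preserved exactly (spaces standing for ISCN "~" modal ranges,
lower-case "46.xx", stray tokens) because the parser is tested against this
real dialect.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass
from typing import Optional

_FIXTURE_SHA256 = "834443faf114cdd89eb0d41430e4500125c225ccc306ecd7629b5772151794c4"


class FixtureError(RuntimeError):
    """Raised when the packaged fixture is missing or corrupted."""


@dataclass(frozen=True)
class Table2Record:
    sample: Optional[int]  # None for the aggregate normal row
    ngs_cnv: str
    karyotype: str
    interpretation: str
    count: int = 1  # >1 only for the aggregate row

    @property
    def is_aggregate(self) -> bool:
        return self.sample is None


def load_table2_fixture() -> list[Table2Record]:
    """Load the packaged fixture: 44 numbered records + 1 aggregate record.

    The aggregate record carries ``count=45`` and represents the
    normal-karyotype samples the source prints only as a tally.  Verifies a
    checksum so silent corruption surfaces as :class:`FixtureError`.
    """
    ref = importlib.resources.files("liquidcnv.data").joinpath("table2.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureError(
            f"table2.tsv checksum mismatch (got {digest[:12]}..., "
            f"expected {_FIXTURE_SHA256[:12]}...)"
        )
    records: list[Table2Record] = []
    lines = raw.decode("utf-8").splitlines()
    for line in lines[1:]:
        sample_s, ngs, kar, interp = line.split("\t")
        if sample_s:
            records.append(Table2Record(int(sample_s), ngs, kar, interp))
        else:
            records.append(Table2Record(None, ngs, kar, interp, count=45))
    if len(records) != 45 or sum(r.count for r in records) != 89:
        raise FixtureError("fixture must hold 44 numbered records + 45 aggregated")
    return records
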