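import pytest

from dirsel.property_table import builtin_library
from dirsel.simulation import sage1_fixture


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture(scope="session")
def hydropathy(library):
    return library["h"]


@pytest.fixture()
def sage1():
    return sage1_fixture()


#: Printed one-decimal hydropathy deltas of the Pan/Homo SAGE1 comparison,
#: under the first-minus-second (from_minus_to) convention.
SAGE1_PRINTED_DELTAS = (
    7.0, 2.4, -1.3, 1.0, -7.7, -0.1, 2.4, 7.7, -1.0, 2.5, 2.7, -2.5, 7.0, 2.4, 4.6,
)


@pytest.fixture(scope="session")
def sage1_printed_deltas():
    return SAGE1_PRINTED_DELTAS


@pytest.fixture()
def sage1_table_text(sage1):
    lines = ["site\tfrom\tto"]
    lines += [f"{r.site}\t{r.from_res}\t{r.to_res}" for r in sage1]
    return "\n".join(lines) + "\n"


@pytest.fixture()
def sage1_pair():
    """Two synthetic 805-residue sequences differing exactly at the 15 sites."""
    fix = sage1_fixture()
    a = ["A"] * fix.sequence_length
    b = ["A"] * fix.sequence_length
    for r in fix:
        a[r.site - 1] = r.from_res
        b[r.site - 1] = r.to_res
    return "".join(a), "".join(b)
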