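import io

import pandas as pd
import pytest

from compositegraph.edge_table import COLUMNS, EdgeTable, read_edge_table

# the single-target ranking example, in full seven-column form
TABLE4_CSV = """source_id,source_name,source_type,target_id,target_name,target_type,edge_value
S4_id,S4,G1,T1_id,T1,T,4
S3_id,S3,G1,T1_id,T1,T,3
S2_id,S2,G1,T1_id,T1,T,2
S1_id,S1,G1,T1_id,T1,T,1
"""

# two sources sharing the display name "S3" under different ids/groups
TABLE3_CSV = """source_id,source_name,source_type,target_id,target_name,target_type,edge_value
S3_2,S3,G2,T1_id,T1,T,3
S3_2,S3,G2,T2_id,T2,T,3
S3_2,S3,G2,T3_id,T3,T,4
S3_1,S3,G1,T1_id,T1,T,3
S3_1,S3,G1,T2_id,T2,T,4
S4_1,S4,G1,T1_id,T1,T,4
S4_1,S4,G1,T2_id,T2,T,2
S1_1,S1,G1,T1_id,T1,T,1
S1_1,S1,G1,T2_id,T2,T,3
S2_1,S2,G1,T1_id,T1,T,2
S2_1,S2,G1,T2_id,T2,T,1
"""

# the 4-sources-by-2-targets example, recast with explicit ids
TABLE2_CSV = """source_id,source_name,source_type,target_id,target_name,target_type,edge_value
S3_id,S3,G1,T1_id,T1,T,3
S3_id,S3,G1,T2_id,T2,T,4
S4_id,S4,G1,T1_id,T1,T,4
S4_id,S4,G1,T2_id,T2,T,2
S1_id,S1,G1,T1_id,T1,T,1
S1_id,S1,G1,T2_id,T2,T,3
S2_id,S2,G1,T1_id,T1,T,2
S2_id,S2,G1,T2_id,T2,T,1
"""


@pytest.fixture
def table4():
    return read_edge_table(io.StringIO(TABLE4_CSV))


@pytest.fixture
def table3():
    return read_edge_table(io.StringIO(TABLE3_CSV))


@pytest.fixture
def table2():
    return read_edge_table(io.StringIO(TABLE2_CSV))


def worked_bounds_table() -> EdgeTable:
    """A graph whose composite scores span exactly [2, 8], containing one
    source with outgoing edges {4, 7, 12} (arithmetic mean 23/3)."""
    rows = [
        ("W", "W", "G", "TA", "TA", "T", 4.0),
        ("W", "W", "G", "TB", "TB", "T", 7.0),
        ("W", "W", "G", "TC", "TC", "T", 12.0),
        ("LOW", "LOW", "G", "TA", "TA", "T", 2.0),
        ("HIGH", "HIGH", "G", "TB", "TB", "T", 8.0),
    ]
    return EdgeTable(pd.DataFrame(rows, columns=list(COLUMNS)))


@pytest.fixture
def worked_table():
    return worked_bounds_table()


def two_target_table(n_exclusive: int = 30, n_shared: int = 20) -> EdgeTable:
    """Two targets with n_exclusive sources each plus n_shared shared sources."""
    rows = []
    for i in range(n_exclusive):
        rows.append((f"A{i:02d}", f"A{i:02d}", "g", "T1", "T1", "t", 1.0))
        rows.append((f"B{i:02d}", f"B{i:02d}", "g", "T2", "T2", "t", 1.0))
    for i in range(n_shared):
        rows.append((f"X{i:02d}", f"X{i:02d}", "g", "T1", "T1", "t", 1.0))
        rows.append((f"X{i:02d}", f"X{i:02d}", "g", "T2", "T2", "t", 1.0))
    return EdgeTable(pd.DataFrame(rows, columns=list(COLUMNS)))


@pytest.fixture
def two_target_view():
    from compositegraph.filtering import apply_filter_cascade

    return apply_filter_cascade(two_target_table())
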