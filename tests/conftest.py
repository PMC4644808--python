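from __future__ import annotations

import pytest

from listwise.core import (
    Background,
    DataType,
    FeatureMeta,
    FeatureTable,
    Theme,
)

CHAIN_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: T:0000001
name: root a
namespace: biological_process

[Term]
id: T:0000002
name: mid b
namespace: biological_process
is_a: T:0000001 ! root a

[Term]
id: T:0000003
name: leaf c
namespace: biological_process
alt_id: T:0000099
is_a: T:0000002 ! mid b

[Term]
id: T:0000004
name: dead term
namespace: biological_process
is_obsolete: true
"""

DIAMOND_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: D:1
name: apex
namespace: biological_process

[Term]
id: D:2
name: left
namespace: biological_process
is_a: D:1

[Term]
id: D:3
name: right
namespace: biological_process
relationship: part_of D:1

[Term]
id: D:4
name: bottom
namespace: biological_process
is_a: D:2
is_a: D:3
"""


@pytest.fixture
def chain_obo() -> str:
    return CHAIN_OBO


@pytest.fixture
def diamond_obo() -> str:
    return DIAMOND_OBO


@pytest.fixture
def background10() -> Background:
    return Background(frozenset(f"g{i}" for i in range(1, 11)), "custom")


def binary_meta(fid: str, theme: Theme = Theme.GENE_EXPRESSION) -> FeatureMeta:
    return FeatureMeta(fid, fid, theme, DataType.BINARY, "test")


def metric_meta(fid: str, theme: Theme = Theme.TRANSCRIPT_FEATURES) -> FeatureMeta:
    return FeatureMeta(fid, fid, theme, DataType.METRIC, "test")


@pytest.fixture
def small_table() -> FeatureTable:
    t = FeatureTable()
    t.add_binary(binary_meta("F1"), {"g1", "g2", "g3"})
    t.add_metric(metric_meta("M1"), {"g1": 1.0, "g2": 2.5})
    return t
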