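from __future__ import annotations

import pytest

import helpers


@pytest.fixture
def chain_dag():
    return helpers.chain_dag()


@pytest.fixture
def diamond_dag():
    return helpers.diamond_dag()


@pytest.fixture
def write_tsv(tmp_path):
    """Write tab-joined rows to a file under tmp_path and return its path."""

    def _write(name: str, rows: list[list[str]]):
        path = tmp_path / name
        path.write_text("\n".join("\t".join(row) for row in rows) + "\n", encoding="utf-8")
        return path

    return _write
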