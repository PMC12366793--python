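"""Shared fixtures: one small synthetic study reused across test modules."""

from __future__ import annotations

import warnings

import pytest

from paoscope.community import filter_otus, require_pao_genes
from paoscope.synth import SynthParams, gen_design, gen_function_table, gen_otu_table


@pytest.fixture(scope="session")
def default_design():
    return gen_design(6, 6)


@pytest.fixture(scope="session")
def small_study(default_design):
    """Default-parameter study (seed 7): OTU table, truth, functions, PAO subset."""
    params = SynthParams(seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = gen_otu_table(default_design, params)
        functions = gen_function_table(table, params)
        filtered, ledger = filter_otus(table)
        pao = require_pao_genes(filtered, functions)
    return {
        "params": params,
        "design": default_design,
        "table": table,
        "truth": truth,
        "functions": functions,
        "filtered": filtered,
        "ledger": ledger,
        "pao": pao,
    }
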