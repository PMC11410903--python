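import numpy as np
import pandas as pd
import pytest

from mrkit.sumstats import CANONICAL, HarmonizedInstrument, SummaryDataset


def make_dataset(rows, trait_name="trait", trait_type="quantitative",
                 case_fraction=None):
    """Build a SummaryDataset from (id, chr, pos, ea, oa, eaf, beta, se, p, n) tuples."""
    df = pd.DataFrame(rows, columns=list(CANONICAL))
    return SummaryDataset(trait_name, trait_type, df, case_fraction)


def make_instruments(gamma, Gamma, gamma_se=None, Gamma_se=None):
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    gamma_se = np.full_like(gamma, 0.01) if gamma_se is None else np.asarray(gamma_se, float)
    Gamma_se = np.full_like(Gamma, 0.05) if Gamma_se is None else np.asarray(Gamma_se, float)
    return [HarmonizedInstrument(f"rs{i+1}", g, gs, G, Gs, "A", "G")
            for i, (g, gs, G, Gs) in enumerate(zip(gamma, gamma_se, Gamma, Gamma_se))]


@pytest.fixture
def exposure_outcome_pair():
    """A tiny exposure/outcome pair covering every harmonization branch."""
    exposure = make_dataset([
        ("rs1", "1", 100, "A", "G", 0.30, 0.10, 0.01, 1e-20, 10000),   # same alleles
        ("rs2", "1", 200, "A", "G", 0.30, 0.10, 0.01, 1e-20, 10000),   # swapped in outcome
        ("rs3", "1", 300, "A", "G", 0.30, 0.10, 0.01, 1e-20, 10000),   # strand complement
        ("rs4", "1", 400, "A", "T", 0.20, 0.10, 0.01, 1e-20, 10000),   # palindromic, clear
        ("rs5", "1", 500, "A", "T", 0.50, 0.10, 0.01, 1e-20, 10000),   # palindromic, ambiguous
        ("rs6", "1", 600, "A", "G", 0.30, 0.10, 0.01, 1e-20, 10000),   # missing from outcome
    ], trait_name="exposure")
    outcome = make_dataset([
        ("rs1", "1", 100, "A", "G", 0.30, 0.05, 0.02, 1e-3, 50000),
        ("rs2", "1", 200, "G", "A", 0.70, 0.05, 0.02, 1e-3, 50000),
        ("rs3", "1", 300, "T", "C", 0.30, 0.05, 0.02, 1e-3, 50000),
        ("rs4", "1", 400, "A", "T", 0.22, 0.04, 0.02, 1e-3, 50000),
        ("rs5", "1", 500, "A", "T", 0.50, 0.04, 0.02, 1e-3, 50000),
    ], trait_name="outcome", trait_type="binary", case_fraction=0.1)
    return exposure, outcome
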