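import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ontomodules import synthetic
from ontomodules.shape_metrics import build_basis

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis30():
    return build_basis(30)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def small_scenario():
    """A shrunk default scenario (600 genes) for fast end-to-end unit tests."""
    cfg = synthetic.default_scenario(seed=1)
    cfg.n_genes = 600
    em, ann, truth = synthetic.generate(cfg)
    return cfg, em, ann, truth


@pytest.fixture()
def toy_counts(tmp_path):
    """3-gene x 4-sample count TSV (2 timepoints x 2 replicates) + sample sheet."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "Geneid\tChr\tLength\ts1\ts2\ts3\ts4\n"
        "gA\tI\t500\t10\t20\t100\t110\n"
        "gB\tII\t800\t0\t5\t50\t40\n"
        "gC\tX\t300\t90\t75\t850\t850\n"
    )
    sheet = tmp_path / "samples.tsv"
    sheet.write_text(
        "sample_id\ttimepoint\tminutes\tstage\treplicate\n"
        "s1\t1\t0\tEE\t1\n"
        "s2\t1\t0\tEE\t2\n"
        "s3\t2\t30\tEE\t1\n"
        "s4\t2\t30\tEE\t2\n"
    )
    return counts, sheet


@pytest.fixture()
def toy_annotation():
    """12-gene annotation frame exercising every attribute family."""
    genes = [f"g{i}" for i in range(12)]
    return pd.DataFrame(
        {
            "chromosome": ["I", "II", "II", "X", "MtDNA", "III", "IV", "V", "II", "X", "I", "III"],
            "domain": ["arm", "center", "arm", "center", pd.NA, "arm", "center", "arm",
                       "center", "arm", "center", "center"],
            "operon": [True, False, True, False, False, True, False, False, True, False,
                       False, True],
            "gamete_class": ["oogenic", "spermatogenic", "sex-neutral", "oogenic", pd.NA,
                            "sex-neutral", "spermatogenic", "sex-neutral", "oogenic",
                            "spermatogenic", "sex-neutral", pd.NA],
            "embryo_category": ["maternal", "transient", pd.NA, "maternal|degradation",
                               pd.NA, "embryonic", pd.NA, "transient", "maternal", pd.NA,
                               "degradation", "embryonic"],
            "has_ortholog": [True, True, False, True, True, True, True, False, True, True,
                            True, True],
            "ka": [0.1, 0.2, np.nan, 0.05, 0.3, 0.0, 0.4, np.nan, 0.15, 0.25, 0.02, 0.08],
            "ks": [1.0, 2.0, np.nan, 0.9, 2.5, 1.1, 3.0, np.nan, 2.2, 2.8, 0.8, 1.5],
        },
        index=pd.Index(genes, name="gene_id"),
    )
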