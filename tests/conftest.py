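import numpy as np
import pandas as pd
import pytest

from looplens import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20150331)


@pytest.fixture
def tiny_transcript():
    """A 1000-nt transcript with moderate loop prevalence and end assays."""
    return simulate.TranscriptSim.from_closed_fraction("T1", 1000, closed_fraction=0.4)


@pytest.fixture
def small_dataset():
    """A small but complete simulated dataset (2 transcripts, 2 bio reps)."""
    cfg = simulate.SimulationConfig(
        transcripts=(
            simulate.TranscriptSim.from_closed_fraction("TA", 1200, 0.3),
            simulate.TranscriptSim.from_closed_fraction("TB", 2000, 0.6),
        ),
        n_molecules=5000,
        n_bio=2,
    )
    return simulate.generate_ct_dataset(cfg, seed=7)


def write_csv(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def csv_writer(tmp_path):
    def _write(name, text):
        return write_csv(tmp_path, name, text)

    return _write


def enrichment_frame(rows):
    """Build an enrichment table from (transcript, factor, cond, rep, assay, cls, raw)."""
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "factor", "condition", "bio_rep", "assay_id", "region_class", "raw"],
    )
    df["se_log"] = np.nan
    df["ci_low"] = df["raw"]
    df["ci_high"] = df["raw"]
    return df
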