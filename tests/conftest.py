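import numpy as np
import pytest

import ribodrop as rd


@pytest.fixture
def tiny_catalog():
    return rd.TranscriptCatalog({"geneA": 120, "geneB": 75})


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records, name="transcripts.fa"):
        path = tmp_path / name
        with open(path, "w") as out:
            for header, seq in records:
                out.write(f">{header}\n{seq}\n")
        return path
    return _write


@pytest.fixture
def bed_file(tmp_path):
    def _write(lines, name="reads.bed"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return path
    return _write


def brute_force_wls(x, y, w):
    """Independent oracle: direct solve of the 2x2 weighted normal equations.

    Minimises sum w_i (y_i - a - b x_i)^2 via the literal normal equations,
    a different route from the centered closed form used by the package.
    """
    x = np.asarray(x, float); y = np.asarray(y, float); w = np.asarray(w, float)
    A = np.array([[w.sum(), (w * x).sum()],
                  [(w * x).sum(), (w * x * x).sum()]])
    b = np.array([(w * y).sum(), (w * x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return slope, intercept
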