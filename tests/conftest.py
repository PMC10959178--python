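import numpy as np
import pytest

from autobcr.io import FluxProtocol
from autobcr.simulate import FluxSimParams, simulate_flux_experiment


@pytest.fixture(scope="session")
def protocol():
    return FluxProtocol()


@pytest.fixture()
def small_signaling_series(protocol):
    """A modest signaling sample with ground truth, for pipeline tests."""
    params = FluxSimParams(n_cells=2000, p_aut=0.6, u_true=0.1, seed=7)
    return simulate_flux_experiment(params, protocol)


def write_minimal_fcs(path, channels: dict[str, np.ndarray], timestep: float = 0.01,
                      version: str = "FCS3.1", datatype: str = "F"):
    """Write a minimal single-dataset list-mode FCS file (test fixture only)."""
    names = list(channels)
    arrs = [np.asarray(channels[n], dtype=np.float32 if datatype == "F" else np.float64)
            for n in names]
    n_tot = len(arrs[0])
    assert all(len(a) == n_tot for a in arrs)
    data = np.column_stack(arrs).astype("<f4" if datatype == "F" else "<f8").tobytes()

    width = 32 if datatype == "F" else 64
    kv = {
        "$MODE": "L", "$DATATYPE": datatype, "$BYTEORD": "1,2,3,4",
        "$PAR": str(len(names)), "$TOT": str(n_tot), "$TIMESTEP": repr(timestep),
        "$NEXTDATA": "0",
    }
    for i, n in enumerate(names, start=1):
        kv[f"$P{i}N"] = n
        kv[f"$P{i}B"] = str(width)
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"

    header_len = 58
    # iterate: text length depends on the data offsets it embeds
    data_begin = 1000
    for _ in range(4):
        kv["$BEGINDATA"] = str(data_begin)
        kv["$ENDDATA"] = str(data_begin + len(data) - 1)
        text = "/" + "".join(f"{k}/{v}/" for k, v in kv.items())
        text_begin = header_len
        text_end = text_begin + len(text) - 1
        new_begin = text_end + 1
        if new_begin == data_begin:
            break
        data_begin = new_begin
    header = (
        version.ljust(6) + " " * 4
        + f"{text_begin:>8d}{text_end:>8d}"
        + f"{data_begin:>8d}{data_begin + len(data) - 1:>8d}"
        + f"{0:>8d}{0:>8d}"
    )
    assert len(header) == header_len
    blob = header.encode("ascii") + text.encode("ascii") + data
    path.write_bytes(blob)
    return path
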