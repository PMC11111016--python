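"""Shared fixtures: small synthetic runs and a minimal mzXML writer."""

from __future__ import annotations

import base64

import numpy as np
import pytest
from hypothesis import settings

from silkms.msdata import Run, Spectrum

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def simple_run():
    """Ten MS1 scans with one centroid at the quinolinium m/z each."""
    spectra = [
        Spectrum(
            rt=i * 0.05,
            mz=np.array([130.0651]),
            intensity=np.array([100.0 + 10.0 * i]),
            scan_window=(120.0, 140.0),
        )
        for i in range(10)
    ]
    return Run(spectra=spectra)


def write_mzxml(path, run: Run) -> None:
    """Write a minimal mzXML 3.2 document (network byte order, 64-bit pairs)."""
    scans = []
    for i, s in enumerate(run.spectra, start=1):
        pairs = np.empty(2 * s.mz.size)
        pairs[0::2] = s.mz
        pairs[1::2] = s.intensity
        payload = base64.b64encode(pairs.astype(">f8").tobytes()).decode()
        attrs = (
            f'num="{i}" msLevel="{s.ms_level}" peaksCount="{s.mz.size}" '
            f'retentionTime="PT{s.rt * 60.0:.6f}S"'
        )
        if s.scan_window is not None:
            attrs += f' lowMz="{s.scan_window[0]}" highMz="{s.scan_window[1]}"'
        scans.append(
            f"<scan {attrs}>"
            '<peaks compressionType="none" compressedLen="0" precision="64" '
            f'byteOrder="network" contentType="m/z-int">{payload}</peaks></scan>'
        )
    doc = (
        '<?xml version="1.0"?>\n'
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
        f'<msRun scanCount="{len(run.spectra)}">\n' + "\n".join(scans) + "\n</msRun>\n</mzXML>"
    )
    path.write_text(doc)
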