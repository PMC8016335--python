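import base64
import struct

import pytest

from zoomsid import load_reference_panels
from zoomsid import assemblage_analysis as aa


@pytest.fixture(scope="session")
def panels():
    return load_reference_panels()


@pytest.fixture(scope="session")
def taxonomy(panels):
    return panels.taxonomy


@pytest.fixture(scope="session")
def tools():
    return aa.load_tool_table()


@pytest.fixture(scope="session")
def fauna():
    return aa.load_faunal_table()


@pytest.fixture(scope="session")
def sampling():
    return aa.load_sampling_table()


# ---------------------------------------------------------------------------
# Minimal mzML writer for fixtures (centroided or profile, 64-bit, uncompressed)

def _b64(values):
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


_MODE_CV = {
    "centroid": ("MS:1000127", "centroid spectrum"),
    "profile": ("MS:1000128", "profile spectrum"),
}


def _spectrum_xml(index, mz, intensity, mode):
    acc, name = _MODE_CV[mode]
    return (
        f'<spectrum index="{index}" id="scan={index + 1}" '
        f'defaultArrayLength="{len(mz)}">'
        f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>'
        '<binaryDataArrayList count="2">'
        '<binaryDataArray>'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>'
        f'<binary>{_b64(mz)}</binary></binaryDataArray>'
        '<binaryDataArray>'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>'
        f'<binary>{_b64(intensity)}</binary></binaryDataArray>'
        '</binaryDataArrayList></spectrum>'
    )


def write_mzml(path, spectra, mode="centroid"):
    """Write a minimal mzML file; spectra = [(mz_list, intensity_list), ...]."""
    body = "".join(_spectrum_xml(i, mz, inten, mode)
                   for i, (mz, inten) in enumerate(spectra))
    path.write_text(
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        f'<run id="r"><spectrumList count="{len(spectra)}">{body}'
        '</spectrumList></run></mzML>', encoding="utf-8")
    return path
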