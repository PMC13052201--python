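import base64
import struct

import pytest

from legscan import library as lib


@pytest.fixture(scope="session")
def scaffold():
    return lib.sfti_scaffold()


@pytest.fixture(scope="session")
def scan_sites():
    return lib.SFTI_SCAN_SITES


def write_mzml(path, mz, intensity):
    """Write a minimal one-spectrum mzML file (64-bit, uncompressed)."""

    def encode(values):
        raw = struct.pack(f"<{len(values)}d", *values)
        return base64.b64encode(raw).decode()

    def array_xml(values, accession, name):
        b64 = encode(values)
        return f"""
      <binaryDataArray encodedLength="{len(b64)}">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>
        <binary>{b64}</binary>
      </binaryDataArray>"""

    xml = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1">
    <spectrumList count="1" defaultDataProcessingRef="dp1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <binaryDataArrayList count="2">{array_xml(mz, "MS:1000514", "m/z array")}{array_xml(intensity, "MS:1000515", "intensity array")}
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""
    path.write_text(xml)
    return path
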