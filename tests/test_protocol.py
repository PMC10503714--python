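"""Command-line parsing, XML request handling, validation, and the session
lifecycle (flag-file semantics)."""

from __future__ import annotations

from pathlib import Path

import pytest

from svengine.equivalence import write_request_xml
from svengine.protocol import (
    CommandLine,
    FlagFileExistsError,
    RequestFormatError,
    RequestValidationError,
    UsageError,
    parse_command_line,
    read_request,
    run_session,
    validate_request,
)
from helpers import base_request_params

EXAMPLE_XML = """<?xml version="1.0" encoding="UTF-8"?>
<cGMPSedfitCall>
  <Model>cofs</Model>
  <Resolution>40</Resolution>
</cGMPSedfitCall>
"""


class TestParseCommandLine:
    def test_full_mode_example(self, tmp_path):
        xml = tmp_path / "TestInput.xml"
        xml.write_text(EXAMPLE_XML)
        cmd = parse_command_line(["111", "handshakestring", str(xml)])
        assert cmd.mode == 111
        assert cmd.handshake == "handshakestring"
        assert cmd.input_path == xml
        assert not cmd.restricted

    def test_restricted_mode_flag(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text(EXAMPLE_XML)
        assert parse_command_line(["112", "x", str(xml)]).restricted

    def test_wrong_arity(self):
        with pytest.raises(UsageError):
            parse_command_line(["111", "x"])
        with pytest.raises(UsageError):
            parse_command_line(["111", "x", "a.xml", "extra"])

    def test_unsupported_mode(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text(EXAMPLE_XML)
        with pytest.raises(UsageError):
            parse_command_line(["42", "x", str(xml)])

    def test_unreadable_input(self, tmp_path):
        with pytest.raises(OSError):
            parse_command_line(["111", "x", str(tmp_path / "missing.xml")])

    def test_empty_handshake_rejected(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text(EXAMPLE_XML)
        with pytest.raises(UsageError):
            parse_command_line(["111", "  ", str(xml)])


class TestReadRequest:
    def test_values_bound_and_defaults_applied(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text(EXAMPLE_XML)
        req = read_request(xml)
        assert req.Model == "cofs"
        assert req.Resolution == 40
        # spike filtering defaults when both parameters are absent
        assert req.FilterDataSpikes is True
        assert req.DataSpikeThreshold == 0.4
        assert req.NumberComputationThreads == 2
        assert req.TINoiseFitted is True and req.RINoiseFitted is True
        assert req.AutoFit is False

    def test_parameter_names_case_sensitive(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text(
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            "<cGMPSedfitCall><model>lsgofs</model></cGMPSedfitCall>"
        )
        req = read_request(xml)
        assert req.Model == "cofs"  # lowercase element ignored, default kept

    def test_malformed_xml_rejected(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text("<cGMPSedfitCall><Model>cofs</Model>")  # unclosed root
        with pytest.raises(RequestFormatError):
            read_request(xml)

    def test_wrong_root_rejected(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text("<SomethingElse><Model>cofs</Model></SomethingElse>")
        with pytest.raises(RequestFormatError):
            read_request(xml)

    def test_unparseable_value_names_parameter(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text("<cGMPSedfitCall><Resolution>many</Resolution></cGMPSedfitCall>")
        with pytest.raises(ValueError, match="Resolution"):
            read_request(xml)

    def test_passthrough_preserved_verbatim_including_markup(self, tmp_path):
        xml = tmp_path / "in.xml"
        xml.write_text(
            "<cGMPSedfitCall><PassThrough><sample><name>A</name>"
            "<lot>7</lot></sample></PassThrough></cGMPSedfitCall>"
        )
        req = read_request(xml)
        assert "<name>A</name>" in req.PassThrough
        assert "<lot>7</lot>" in req.PassThrough


class TestValidateRequest:
    def _valid(self, tmp_path, data_dir):
        return read_request(
            write_request_xml(tmp_path / "r.xml", base_request_params(data_dir, tmp_path))
        )

    def test_valid_request_no_violations(self, tmp_path, small_dataset):
        data_dir, *_ = small_dataset
        assert validate_request(self._valid(tmp_path, data_dir)) == []

    @pytest.mark.parametrize(
        "name,value,fragment",
        [
            ("RegularizationPvalue", 0.3, "0.5"),
            ("MeniscusUpperLimit", 5.99, "Meniscus"),
            ("Smin", 15.0, "Smin"),
            ("Smax", 1.0, "Smin"),
            ("Model", "unknown", "Model"),
            ("FirstScan", 99, "FirstScan"),
            ("RightFitLimit", 7.5, "Bottom"),
        ],
    )
    def test_single_violation_reported(self, tmp_path, small_dataset, name, value, fragment):
        data_dir, *_ = small_dataset
        req = self._valid(tmp_path, data_dir)
        setattr(req, name, value)
        violations = validate_request(req)
        assert violations, f"expected a violation for {name}={value}"
        assert any(fragment in v for v in violations)

    def test_restricted_mode_rejects_nonstandard_options(self, tmp_path, small_dataset):
        data_dir, *_ = small_dataset
        req = self._valid(tmp_path, data_dir)
        req.GridfromFile = True
        req.UseLogSpaceSgrid = True
        req.BottomFitted = True
        assert validate_request(req, restricted=False) == []
        violations = validate_request(req, restricted=True)
        assert len(violations) == 3
        assert all("112" in v for v in violations)


@pytest.fixture(scope="module")
def completed(small_dataset, tmp_path_factory):
    data_dir, *_ = small_dataset
    work = tmp_path_factory.mktemp("session")
    params = base_request_params(data_dir, work, tag="run")
    xml = write_request_xml(work / "request.xml", params)
    cmd = CommandLine(mode=111, handshake="hs-42", input_path=xml)
    result = run_session(cmd)
    return work, params, result


class TestRunSession:
    def test_flag_file_contains_exactly_handshake(self, completed):
        work, params, _ = completed
        content = Path(params["AllDoneFlagFile"]).read_text()
        assert content == "hs-42\n"

    def test_output_directory_created_and_populated(self, completed):
        work, params, _ = completed
        out = Path(params["OutputResultsDirectory"])
        assert out.is_dir()
        names = sorted(p.name for p in out.iterdir())
        assert names == sorted(
            [
                "screenshot.bmp", "RInoise.dat", "TInoise.dat", "ScanRMSD.dat",
                "distribution.dat", "dfr.dat", "ResultParameters.xml",
            ]
        )

    def test_sdist_written_next_to_data(self, completed, small_dataset):
        data_dir, *_ = small_dataset
        lines = (data_dir / "sdist.ra2").read_text().strip().splitlines()
        assert len(lines) == 21  # Resolution of the request

    def test_result_echoes_request_state(self, completed):
        _, params, result = completed
        assert result.request.Model == "cofs"
        assert result.stats.RMSD > 0
        assert result.metadata.RotorSpeed == 50000

    def test_preexisting_flag_file_refused(self, small_dataset, tmp_path):
        data_dir, *_ = small_dataset
        params = base_request_params(data_dir, tmp_path, tag="pre")
        Path(params["AllDoneFlagFile"]).write_text("stale")
        xml = write_request_xml(tmp_path / "request.xml", params)
        with pytest.raises((RequestValidationError, FlagFileExistsError)):
            run_session(CommandLine(mode=111, handshake="x", input_path=xml))
        assert not Path(params["OutputResultsDirectory"]).exists()

    def test_validation_failure_leaves_no_outputs(self, small_dataset, tmp_path):
        data_dir, *_ = small_dataset
        params = base_request_params(data_dir, tmp_path, tag="bad")
        params["RegularizationPvalue"] = 0.1
        xml = write_request_xml(tmp_path / "request.xml", params)
        with pytest.raises(RequestValidationError):
            run_session(CommandLine(mode=111, handshake="x", input_path=xml))
        assert not Path(params["AllDoneFlagFile"]).exists()
        assert not Path(params["OutputResultsDirectory"]).exists()

    def test_mode_112_rejects_nonstandard_request(self, small_dataset, tmp_path):
        data_dir, *_ = small_dataset
        params = base_request_params(data_dir, tmp_path, tag="m112")
        params["UseLogSpaceSgrid"] = True
        xml = write_request_xml(tmp_path / "request.xml", params)
        with pytest.raises(RequestValidationError, match="112"):
            run_session(CommandLine(mode=112, handshake="x", input_path=xml))
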