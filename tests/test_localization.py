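"""Onset/terminal extraction, laterality rules and topographic rendering."""

import numpy as np
import pytest

from sozdetect.detection import DetectionMatrix
from sozdetect.localization import (
    BOTH_HEMISPHERES,
    FOCAL,
    GENERALIZED,
    LEFT_HEMISPHERE,
    RIGHT_HEMISPHERE,
    LateralityError,
    analyze_matrix,
    classify_seizure_type,
    classify_soz,
    onset_sites,
    render_state,
    render_topomap,
    terminal_sites,
)
from sozdetect.montage import CANONICAL_SITES, MIDLINE, hemisphere_of, standard_layout


def make_matrix(flags: dict[int, set[str]], seconds: int = 40) -> DetectionMatrix:
    """Build a matrix from {second: flagged sites}."""
    verdicts = np.zeros((21, seconds), dtype=int)
    for second, sites in flags.items():
        for site in sites:
            verdicts[CANONICAL_SITES.index(site), second] = 1
    return DetectionMatrix(
        site_names=list(CANONICAL_SITES), verdicts=verdicts,
        probabilities=verdicts.astype(float),
    )


@pytest.fixture
def right_onset_matrix():
    """Right-hemisphere onset at t=15 that spreads and ends frontally right."""
    onset = {"Pz", "C4", "P4", "F8", "T4"}
    flags = {t: onset for t in range(15, 18)}
    flags[18] = flags[19] = onset | {"F4", "T6"}
    for t in range(20, 33):
        flags[t] = set(CANONICAL_SITES)  # full spread
    flags[33] = {"F4", "F8"}
    flags[34] = {"F4", "F8"}
    return make_matrix(flags)


def test_hemisphere_tagging_convention():
    for site in CANONICAL_SITES:
        h = hemisphere_of(site)
        if site.endswith("z"):
            assert h == MIDLINE
        elif int(site[-1]) % 2:
            assert h == "left"
        else:
            assert h == "right"


def test_onset_extraction(right_onset_matrix):
    second, sites = onset_sites(right_onset_matrix)
    assert second == 15
    assert sites == {"Pz", "C4", "P4", "F8", "T4", "F4", "T6"}
    # narrower window excludes the later joiners
    _, tight = onset_sites(right_onset_matrix, onset_window_s=2)
    assert tight == {"Pz", "C4", "P4", "F8", "T4"}


def test_onset_single_flag_and_empty():
    single = make_matrix({7: {"F7"}})
    assert onset_sites(single) == (7, {"F7"})
    with pytest.raises(ValueError):
        onset_sites(make_matrix({}))


def test_terminal_extraction(right_onset_matrix):
    assert terminal_sites(right_onset_matrix, terminal_window_s=2) == {"F4", "F8"}


def test_terminal_full_scalp_at_last_second():
    m = make_matrix({10: set(CANONICAL_SITES)}, seconds=12)
    assert terminal_sites(m) == set(CANONICAL_SITES)
    with pytest.raises(ValueError):
        terminal_sites(make_matrix({}))


class TestLateralityRules:
    def test_right_hemisphere_onset_with_midline_site(self):
        onset = {"Pz", "C4", "P4", "F8", "T4"}
        assert classify_soz(onset, {"F4", "F8"}) == RIGHT_HEMISPHERE
        assert classify_seizure_type(onset) == FOCAL

    def test_bilateral_onset(self):
        onset = {"F7", "F3", "C3", "T3", "F4", "C4", "T4", "F8"}
        assert classify_soz(onset, set()) == BOTH_HEMISPHERES
        assert classify_seizure_type(onset) == GENERALIZED

    def test_posterior_bilateral_onset(self):
        onset = {"O1", "O2", "T5", "T6", "P4"}
        assert classify_seizure_type(onset) == GENERALIZED
        assert classify_soz(onset, set()) == BOTH_HEMISPHERES

    def test_single_lateralized_site_is_focal(self):
        assert classify_seizure_type({"F7"}) == FOCAL
        assert classify_soz({"F7"}, set()) == LEFT_HEMISPHERE

    def test_midline_only_onset_is_indeterminate(self):
        with pytest.raises(LateralityError):
            classify_soz({"Cz"}, {"Cz"})
        with pytest.raises(LateralityError):
            classify_seizure_type({"Pz", "Fz"})

    def test_ear_electrodes_vote(self):
        assert classify_soz({"A1", "T3"}, set()) == LEFT_HEMISPHERE

    def test_terminal_refines_but_never_overrides_onset(self):
        # unilateral right onset stays right even if spread reaches the left
        assert classify_soz({"F8", "T4"}, {"F7", "F8"}) == RIGHT_HEMISPHERE

    def test_mirror_symmetry(self):
        layout = standard_layout()
        onset = {"Pz", "C4", "P4", "F8", "T4"}
        terminal = {"F4", "F8"}
        mirrored_on = {layout.mirror_site(s) for s in onset}
        mirrored_term = {layout.mirror_site(s) for s in terminal}
        assert classify_soz(onset, terminal) == RIGHT_HEMISPHERE
        assert classify_soz(mirrored_on, mirrored_term) == LEFT_HEMISPHERE


def test_analyze_matrix_end_to_end(right_onset_matrix):
    report = analyze_matrix(right_onset_matrix)
    assert report.onset_second == 15
    assert report.soz_verdict == RIGHT_HEMISPHERE
    assert report.seizure_type == FOCAL
    assert report.terminal_sites <= set(CANONICAL_SITES)


def test_render_state(right_onset_matrix):
    state = render_state(right_onset_matrix, 15)
    assert sum(state.values()) == 5
    assert state["F8"] and not state["F7"]
    quiet = render_state(right_onset_matrix, 0)
    assert not any(quiet.values())
    single = render_state(make_matrix({3: {"F8"}}), 3)
    assert [s for s, on in single.items() if on] == ["F8"]
    with pytest.raises(ValueError):
        render_state(right_onset_matrix, 99)


def test_render_topomap_writes_panels(tmp_path, right_onset_matrix):
    seconds = [15, 18, 25, 30, 34]
    paths = render_topomap(right_onset_matrix, seconds, out_dir=tmp_path)
    assert len(paths) == 6  # five per-second panels + one sequence sheet
    assert all(p.exists() and p.stat().st_size > 0 for p in paths)
    with pytest.raises(ValueError):
        render_topomap(right_onset_matrix, [99], out_dir=tmp_path)
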