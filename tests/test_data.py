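"""YOLO-label IO, splitting, mosaic and letterbox."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marrowdet.data import (
    Annotation,
    DatasetIndex,
    LabelParseError,
    letterbox,
    mosaic_augment,
    read_yolo_labels,
    split_dataset,
    unletterbox_box,
    write_yolo_labels,
)


def test_label_literal_parse(tmp_path):
    p = tmp_path / "a.txt"
    p.write_text("3 0.5 0.5 0.09 0.09\n")
    anns = read_yolo_labels(p)
    assert anns == [Annotation(3, 0.5, 0.5, 0.09, 0.09)]


def test_empty_file_gives_empty_list(tmp_path):
    p = tmp_path / "empty.txt"
    p.write_text("")
    assert read_yolo_labels(p) == []


@pytest.mark.parametrize(
    "line", ["3 0.5 0.5 0.09", "x 0.5 0.5 0.1 0.1", "3 0.5 0.5 a 0.1"]
)
def test_malformed_line_names_file_and_lineno(tmp_path, line):
    p = tmp_path / "bad.txt"
    p.write_text("0 0.5 0.5 0.1 0.1\n" + line + "\n")
    with pytest.raises(LabelParseError, match=r"bad\.txt:2"):
        read_yolo_labels(p)


def test_class_id_out_of_range_rejected(tmp_path):
    p = tmp_path / "oob.txt"
    p.write_text("15 0.5 0.5 0.1 0.1\n")
    with pytest.raises(LabelParseError):
        read_yolo_labels(p, num_classes=15)


@settings(max_examples=25, deadline=None)
@given(st.lists(
    st.tuples(
        st.integers(0, 14),
        st.floats(0.2, 0.8), st.floats(0.2, 0.8),
        st.floats(0.01, 0.3), st.floats(0.01, 0.3),
    ),
    min_size=1, max_size=100,
))
def test_label_roundtrip_stable_to_six_decimals(tmp_path_factory, rows):
    anns = [Annotation(c, round(cx, 6), round(cy, 6), round(w, 6), round(h, 6))
            for c, cx, cy, w, h in rows]
    p = tmp_path_factory.mktemp("rt") / "labels.txt"
    write_yolo_labels(p, anns)
    back = read_yolo_labels(p)
    assert len(back) == len(anns)
    for a, b in zip(anns, back):
        assert a.class_id == b.class_id
        for attr in ("cx", "cy", "w", "h"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-6)
    # second round trip is bit-stable
    p2 = p.with_suffix(".2.txt")
    write_yolo_labels(p2, back)
    assert p.read_text() == p2.read_text()


def _index(n):
    return DatasetIndex([f"img{i}.png" for i in range(n)],
                        [f"img{i}.txt" for i in range(n)], ["a", "b"])


def test_split_sizes_disjoint_and_deterministic():
    idx = _index(1000)
    tr, va = split_dataset(idx, ratio=0.7, seed=3)
    assert len(tr) == 700 and len(va) == 300
    assert set(tr.image_paths).isdisjoint(va.image_paths)
    tr2, va2 = split_dataset(idx, ratio=0.7, seed=3)
    assert tr.image_paths == tr2.image_paths
    with pytest.raises(ValueError):
        split_dataset(_index(1), 0.7)
    with pytest.raises(ValueError):
        split_dataset(idx, 1.5)


# --------------------------------------------------------------------- mosaic
def _solid(color, size=100, anns=()):
    img = np.full((size, size, 3), color, dtype=np.uint8)
    return img, list(anns)


def test_mosaic_stitches_four_colors_around_center():
    samples = [_solid(c) for c in (10, 60, 120, 200)]
    rng = np.random.default_rng(0)
    img, anns = mosaic_augment(samples, 128, rng)
    assert img.shape == (128, 128, 3)
    colors = {10, 60, 120, 200, 114}  # tiles + pad fill
    assert set(np.unique(img)).issubset(colors)
    assert anns == []
    with pytest.raises(ValueError):
        mosaic_augment(samples[:3], 128, rng)


def test_mosaic_box_maps_by_tile_affine():
    ann = Annotation(2, 0.5, 0.5, 0.2, 0.2)
    samples = [_solid(50, anns=[ann]) for _ in range(4)]
    rng = np.random.default_rng(1)
    img, anns = mosaic_augment(samples, 160, rng)
    # replay the rng draws to reconstruct each tile's affine transform
    rng2 = np.random.default_rng(1)
    s = 160
    xc = int(rng2.uniform(0.25, 0.75) * s)
    yc = int(rng2.uniform(0.25, 0.75) * s)
    expected = []
    corners = {0: lambda nw, nh: (xc - nw, yc - nh), 1: lambda nw, nh: (xc, yc - nh),
               2: lambda nw, nh: (xc - nw, yc), 3: lambda nw, nh: (xc, yc)}
    for tile in range(4):
        scale = rng2.uniform(0.5, 1.5) * s / 100
        nw = nh = max(1, int(100 * scale))
        dx, dy = corners[tile](nw, nh)
        bx1, by1 = 40 * scale + dx, 40 * scale + dy
        bx2, by2 = 60 * scale + dx, 60 * scale + dy
        # clip to canvas/tile visibility
        cx1, cy1 = max(bx1, 0), max(by1, 0)
        cx2, cy2 = min(bx2, s), min(by2, s)
        area0 = (bx2 - bx1) * (by2 - by1)
        if cx2 > cx1 and cy2 > cy1 and (cx2 - cx1) * (cy2 - cy1) >= 0.1 * area0:
            expected.append((cx1, cy1, cx2, cy2))
    got = sorted(a.to_xyxy(s, s) for a in anns)
    assert len(got) == len(sorted(expected))
    for g, e in zip(got, sorted(expected)):
        assert g == pytest.approx(e, abs=1e-3)


def test_mosaic_deterministic_given_seed_and_preserves_classes():
    ann_sets = [[Annotation(i, 0.5, 0.5, 0.3, 0.3)] for i in range(4)]
    samples = [_solid(30 * (i + 1), anns=ann_sets[i]) for i in range(4)]
    img1, a1 = mosaic_augment(samples, 128, np.random.default_rng(9))
    img2, a2 = mosaic_augment(samples, 128, np.random.default_rng(9))
    assert np.array_equal(img1, img2) and a1 == a2
    # class histogram of outputs is a sub-multiset of inputs
    in_classes = [a.class_id for anns in ann_sets for a in anns]
    assert all(a.class_id in in_classes for a in a1)
    # inputs are not mutated
    assert ann_sets[0] == [Annotation(0, 0.5, 0.5, 0.3, 0.3)]


# ------------------------------------------------------------------ letterbox
def test_letterbox_square_upscale():
    img = np.zeros((600, 600, 3), np.uint8)
    canvas, scale, pad = letterbox(img, 640)
    assert canvas.shape == (640, 640, 3)
    assert scale == pytest.approx(640 / 600)
    assert pad == (0, 0)
    with pytest.raises(ValueError):
        letterbox(img, 100)


def test_letterbox_pads_with_gray_and_roundtrips_boxes():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, (300, 500, 3), dtype=np.uint8)
    canvas, scale, pad = letterbox(img, 640)
    assert (canvas[0] == 114).all()  # top padding row
    for _ in range(20):
        x1, y1 = rng.uniform(0, 400), rng.uniform(0, 200)
        box = (x1, y1, x1 + 50, y1 + 60)
        mapped = tuple(v * scale + (pad[0] if i % 2 == 0 else pad[1])
                       for i, v in enumerate(box))
        back = unletterbox_box(mapped, scale, pad)
        assert np.allclose(back, box, atol=0.5)
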