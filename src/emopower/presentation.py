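"""Stimulus-presentation geometry and timing arithmetic.

The experiment drives a steady-state response by flickering the monitor
border to black every 8th refresh of a 60 Hz display (7.5 Hz), crossfades
the scrambled baseline into the real video over 12 frames of 24 fps video
(0.5 s), and presents stimuli over 7 x 12 inches at 120 cm viewing distance.
"""

from __future__ import annotations

import math

MONITOR_REFRESH_HZ = 60.0
FLICKER_EVERY_N_REFRESHES = 8
VIDEO_FPS = 24.0
CROSSFADE_FRAMES = 12
STIMULUS_SIZE_IN = (7.0, 12.0)        # height x width, inches
VIEWING_DISTANCE_CM = 120.0
SCENE_EPOCH_S = (-0.125, 2.0)
VIDEO_EPOCH_S = (-2.0, 10.0)
VIDEO_ANALYSIS_WINDOW_S = (1.0, 9.0)
LPP_WINDOW_S = (0.4, 0.9)

_CM_PER_INCH = 2.54


def flicker_frequency_hz(refresh_hz: float = MONITOR_REFRESH_HZ,
                         every_n: int = FLICKER_EVERY_N_REFRESHES) -> float:
    """Driving frequency of a border flickered every ``every_n`` refreshes."""
    return refresh_hz / every_n


def crossfade_duration_s(frames: int = CROSSFADE_FRAMES,
                         fps: float = VIDEO_FPS) -> float:
    """Duration of the scrambled-to-real video crossfade."""
    return frames / fps


def visual_angle_deg(size_in: float, distance_cm: float = VIEWING_DISTANCE_CM) -> float:
    """Full visual angle subtended by an extent of ``size_in`` inches."""
    half_cm = size_in * _CM_PER_INCH / 2.0
    return 2.0 * math.degrees(math.atan(half_cm / distance_cm))


def fft_bin_width_hz(window_s: tuple = VIDEO_ANALYSIS_WINDOW_S) -> float:
    """Frequency resolution of a rectangular-window FFT over the analysis
    epoch; an 8 s window gives 0.125 Hz so 7.5 Hz is bin-exact."""
    return 1.0 / (window_s[1] - window_s[0])
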