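{
  "comment": "Joint offsets as fractions of standing height: [lateral x, vertical y, longitudinal z]. Left/right symmetric in x. Loosely follows classical body-segment proportion tables (shoulder height 0.818H, hip height 0.53H, shoulder half-width 0.1295H, hip half-width 0.0955H).",
  "offsets": {
    "HipCenter":      [ 0.0,     0.53,  0.0 ],
    "Spine":          [ 0.0,     0.65,  0.0 ],
    "ShoulderCenter": [ 0.0,     0.818, 0.0 ],
    "Head":           [ 0.0,     0.936, 0.0 ],
    "ShoulderLeft":   [-0.1295,  0.818, 0.0 ],
    "ElbowLeft":      [-0.1295,  0.63,  0.0 ],
    "WristLeft":      [-0.1295,  0.49,  0.0 ],
    "HandLeft":       [-0.1295,  0.46,  0.0 ],
    "ShoulderRight":  [ 0.1295,  0.818, 0.0 ],
    "ElbowRight":     [ 0.1295,  0.63,  0.0 ],
    "WristRight":     [ 0.1295,  0.49,  0.0 ],
    "HandRight":      [ 0.1295,  0.46,  0.0 ],
    "HipLeft":        [-0.0955,  0.53,  0.0 ],
    "KneeLeft":       [-0.0955,  0.285, 0.0 ],
    "AnkleLeft":      [-0.0955,  0.039, 0.0 ],
    "FootLeft":       [-0.0955,  0.0,   0.05],
    "HipRight":       [ 0.0955,  0.53,  0.0 ],
    "KneeRight":      [ 0.0955,  0.285, 0.0 ],
    "AnkleRight":     [ 0.0955,  0.039, 0.0 ],
    "FootRight":      [ 0.0955,  0.0,   0.05]
  }
}
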