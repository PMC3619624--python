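{
 "format": "fadsync-mixture",
 "version": 1,
 "comment": "Published five-component reference mixture of the three most significant factor coordinates for a 23-subject normal-contraction control population. Weights sum to 0.999 as printed (renormalized on load); the second covariance is the symmetrized form of the printed matrix.",
 "family": "VVV",
 "R": 5,
 "weights": [0.154, 0.443, 0.139, 0.169, 0.094],
 "means": [
  [0.336, -1.080, 0.010],
  [1.661, -2.524, -0.036],
  [2.504, -1.096, -0.794],
  [0.759, -3.283, 0.160],
  [2.710, -2.652, 1.448]
 ],
 "covariances": [
  [[0.131, -0.077, -0.003],
   [-0.077, 0.387, 0.027],
   [-0.003, 0.027, 1.047]],
  [[0.179, -0.0105, -0.1045],
   [-0.0105, 1.352, 0.788],
   [-0.1045, 0.788, 2.818]],
  [[0.231, 0.087, -0.168],
   [0.087, 0.567, 0.516],
   [-0.168, 0.516, 5.219]],
  [[0.165, -0.425, -0.026],
   [-0.425, 1.763, 0.290],
   [-0.026, 0.290, 2.120]],
  [[0.283, 0.612, -0.533],
   [0.612, 2.479, -0.641],
   [-0.533, -0.641, 3.157]]
 ],
 "fit": null
}
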