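{
 "name": "h36m17",
 "version": 1,
 "joints": [
  {
   "name": "pelvis",
   "side": "center",
   "parent": null,
   "index": 0
  },
  {
   "name": "right_hip",
   "side": "right",
   "parent": "pelvis",
   "index": 1
  },
  {
   "name": "right_knee",
   "side": "right",
   "parent": "right_hip",
   "index": 2
  },
  {
   "name": "right_ankle",
   "side": "right",
   "parent": "right_knee",
   "index": 3
  },
  {
   "name": "right_foot",
   "side": "right",
   "parent": "right_ankle",
   "index": 4
  },
  {
   "name": "left_hip",
   "side": "left",
   "parent": "pelvis",
   "index": 5
  },
  {
   "name": "left_knee",
   "side": "left",
   "parent": "left_hip",
   "index": 6
  },
  {
   "name": "left_ankle",
   "side": "left",
   "parent": "left_knee",
   "index": 7
  },
  {
   "name": "left_foot",
   "side": "left",
   "parent": "left_ankle",
   "index": 8
  },
  {
   "name": "thorax",
   "side": "center",
   "parent": "pelvis",
   "index": 9
  },
  {
   "name": "nose",
   "side": "center",
   "parent": "thorax",
   "index": 10
  },
  {
   "name": "left_shoulder",
   "side": "left",
   "parent": "thorax",
   "index": 11
  },
  {
   "name": "left_elbow",
   "side": "left",
   "parent": "left_shoulder",
   "index": 12
  },
  {
   "name": "left_wrist",
   "side": "left",
   "parent": "left_elbow",
   "index": 13
  },
  {
   "name": "right_shoulder",
   "side": "right",
   "parent": "thorax",
   "index": 14
  },
  {
   "name": "right_elbow",
   "side": "right",
   "parent": "right_shoulder",
   "index": 15
  },
  {
   "name": "right_wrist",
   "side": "right",
   "parent": "right_elbow",
   "index": 16
  }
 ]
}
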