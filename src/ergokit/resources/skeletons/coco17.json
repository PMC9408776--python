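{
 "name": "coco17",
 "version": 1,
 "joints": [
  {
   "name": "nose",
   "side": "center",
   "parent": null,
   "index": 0
  },
  {
   "name": "left_eye",
   "side": "left",
   "parent": "nose",
   "index": 1
  },
  {
   "name": "right_eye",
   "side": "right",
   "parent": "nose",
   "index": 2
  },
  {
   "name": "left_ear",
   "side": "left",
   "parent": "left_eye",
   "index": 3
  },
  {
   "name": "right_ear",
   "side": "right",
   "parent": "right_eye",
   "index": 4
  },
  {
   "name": "left_shoulder",
   "side": "left",
   "parent": null,
   "index": 5
  },
  {
   "name": "right_shoulder",
   "side": "right",
   "parent": null,
   "index": 6
  },
  {
   "name": "left_elbow",
   "side": "left",
   "parent": "left_shoulder",
   "index": 7
  },
  {
   "name": "right_elbow",
   "side": "right",
   "parent": "right_shoulder",
   "index": 8
  },
  {
   "name": "left_wrist",
   "side": "left",
   "parent": "left_elbow",
   "index": 9
  },
  {
   "name": "right_wrist",
   "side": "right",
   "parent": "right_elbow",
   "index": 10
  },
  {
   "name": "left_hip",
   "side": "left",
   "parent": null,
   "index": 11
  },
  {
   "name": "right_hip",
   "side": "right",
   "parent": null,
   "index": 12
  },
  {
   "name": "left_knee",
   "side": "left",
   "parent": "left_hip",
   "index": 13
  },
  {
   "name": "right_knee",
   "side": "right",
   "parent": "right_hip",
   "index": 14
  },
  {
   "name": "left_ankle",
   "side": "left",
   "parent": "left_knee",
   "index": 15
  },
  {
   "name": "right_ankle",
   "side": "right",
   "parent": "right_knee",
   "index": 16
  }
 ]
}
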