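table,n_pairs,z,r
T1,22,-3.945,-0.595
T1,22,-3.1,-0.467
T1,22,-2.029,-0.306
T1,22,-1.737,-0.262
T1,22,-4.01,-0.605
T1,22,-3.1,-0.467
T1,22,-4.042,-0.609
T1,22,-4.107,-0.619
T1,22,-3.685,-0.556
T1,22,-2.808,-0.423
T1,22,-1.737,-0.262
T1,22,-1.315,-0.198
T1,22,-3.847,-0.58
T1,22,-1.672,-0.252
T1,22,-3.847,-0.58
T1,22,-3.912,-0.59
T1,22,-3.1,-0.467
T1,22,-3.36,-0.507
T1,22,-3.036,-0.458
T1,22,-2.646,-0.399
T1,22,-3.912,-0.59
T1,22,-3.847,-0.58
T1,22,-3.977,-0.6
T1,22,-4.074,-0.614
T1,22,-3.36,-0.507
T1,22,-1.51,-0.228
T1,22,-0.568,-0.086
T1,22,-2.062,-0.311
T1,22,-3.393,-0.512
T1,22,-2.451,-0.37
T1,22,-3.295,-0.497
T1,22,-3.523,-0.531
T1,22,-1.607,-0.242
T1,22,-2.711,-0.409
T1,22,-3.165,-0.477
T1,22,-2.289,-0.345
T1,22,-2.289,-0.345
T1,22,-0.828,-0.125
T1,22,-0.536,-0.081
T1,22,-0.016,-0.002
T1,22,-0.243,-0.037
T1,22,-2.289,-0.345
T1,22,-1.217,-0.183
T1,22,-1.542,-0.232
T1,22,-0.243,-0.037
T1,22,-0.925,-0.139
T1,22,-0.016,-0.002
T1,22,-0.146,-0.022
T1,22,-3.587,-0.541
T1,22,-1.347,-0.203
T1,22,-3.328,-0.502
T1,22,-0.86,-0.13
T1,22,-3.977,-0.6
T1,22,-3.782,-0.57
T1,22,-4.074,-0.614
T1,22,-4.042,-0.609
T1,22,-1.445,-0.218
T1,22,-1.25,-0.188
T1,22,-0.373,-0.056
T1,22,-0.828,-0.125
T1,22,-0.601,-0.091
T1,22,-1.542,-0.232
T1,22,-0.73,-0.11
T1,22,-1.899,-0.286
T1,22,-4.107,-0.619
T1,22,-3.036,-0.458
T1,22,-3.036,-0.458
T1,22,-2.678,-0.404
T1,22,-3.945,-0.595
T1,22,-3.393,-0.512
T1,22,-4.107,-0.619
T1,22,-3.977,-0.6
T1,22,-3.263,-0.492
T1,22,-0.211,-0.032
T1,22,-0.016,-0.002
T1,22,-0.179,-0.027
T1,22,-3.165,-0.477
T1,22,-0.146,-0.022
T1,22,-3.393,-0.512
T1,22,-3.068,-0.463
T1,22,-0.73,-0.11
T1,22,-0.016,-0.002
T1,22,-0.341,-0.051
T1,22,-0.373,-0.056
T1,22,-0.763,-0.115
T1,22,-0.438,-0.066
T1,22,-0.179,-0.027
T1,22,-0.308,-0.046
T2,21,-4.015,-0.62
T2,21,-2.45,-0.378
T2,21,-2.694,-0.416
T2,21,-2.485,-0.383
T2,21,-4.015,-0.62
T2,21,-2.972,-0.459
T2,21,-4.015,-0.62
T2,21,-4.015,-0.62
T2,21,-3.98,-0.614
T2,21,-2.589,-0.399
T2,21,-3.285,-0.507
T2,21,-3.319,-0.512
T2,21,-4.015,-0.62
T2,21,-3.493,-0.539
T2,21,-3.98,-0.614
T2,21,-3.945,-0.609
T2,21,-3.98,-0.614
T2,21,-3.493,-0.539
T2,21,-3.25,-0.501
T2,21,-3.041,-0.469
T2,21,-4.015,-0.62
T2,21,-3.875,-0.598
T2,21,-4.015,-0.62
T2,21,-4.015,-0.62
T2,21,-3.841,-0.593
T2,21,-0.504,-0.078
T2,21,-1.095,-0.169
T2,21,-3.041,-0.469
T2,21,-3.076,-0.475
T2,21,-3.389,-0.523
T2,21,-3.041,-0.469
T2,21,-3.736,-0.576
T2,21,-2.763,-0.426
T2,21,-3.285,-0.507
T2,21,-2.728,-0.421
T2,21,-3.319,-0.512
T2,21,-3.215,-0.496
T2,21,-0.122,-0.019
T2,21,-2.346,-0.362
T2,21,-1.199,-0.185
T2,21,-3.563,-0.55
T2,21,-3.875,-0.598
T2,21,-3.18,-0.491
T2,21,-2.694,-0.416
T2,21,-2.381,-0.367
T2,21,-1.616,-0.249
T2,21,-1.929,-0.298
T2,21,-2.033,-0.314
T2,21,-2.381,-0.367
T2,21,-3.319,-0.512
T2,21,-1.964,-0.303
T2,21,-3.91,-0.603
T2,21,-3.424,-0.528
T2,21,-2.346,-0.362
T2,21,-3.806,-0.587
T2,21,-3.597,-0.555
T2,21,-1.199,-0.185
T2,21,-0.678,-0.105
T2,21,-0.33,-0.051
T2,21,-0.226,-0.035
T2,21,-0.539,-0.083
T2,21,-1.929,-0.298
T2,21,-0.678,-0.105
T2,21,-2.485,-0.383
T2,21,-3.736,-0.576
T2,21,-2.52,-0.389
T2,21,-2.242,-0.346
T2,21,-1.825,-0.282
T2,21,-3.667,-0.566
T2,21,-3.007,-0.464
T2,21,-3.493,-0.539
T2,21,-3.563,-0.55
T2,21,-1.025,-0.158
T2,21,-0.295,-0.046
T2,21,-0.017,-0.003
T2,21,-0.226,-0.035
T2,21,-0.469,-0.072
T2,21,-0.052,-0.008
T2,21,-0.226,-0.035
T2,21,-0.608,-0.094
T2,21,-1.095,-0.169
T2,21,-0.052,-0.008
T2,21,-0.956,-0.148
T2,21,-0.504,-0.078
T2,21,-1.025,-0.158
T2,21,-1.13,-0.174
T2,21,-1.06,-0.164
T2,21,-1.616,-0.249
T3,22,-3.62,-0.546
T3,22,-1.217,-0.183
T3,22,-3.425,-0.516
T3,22,-2.841,-0.428
T3,22,-2.419,-0.365
T3,22,-2.808,-0.423
T3,22,-3.685,-0.556
T3,22,-2.646,-0.399
T3,22,-1.25,-0.188
T3,22,-0.958,-0.144
T3,22,-0.308,-0.046
T3,22,-0.828,-0.125
T3,22,-3.036,-0.458
T3,22,-3.555,-0.536
T3,22,-1.055,-0.159
T3,22,-2.354,-0.355
T3,22,-0.049,-0.007
T3,22,-4.074,-0.614
T3,22,-2.484,-0.374
T3,22,-1.704,-0.257
T3,22,-2.289,-0.345
T3,22,-1.412,-0.213
T3,22,-1.899,-0.286
T3,22,-0.601,-0.091
T3,22,-2.386,-0.36
T3,22,-3.88,-0.585
T3,22,-0.86,-0.13
T3,22,-0.925,-0.139
T3,22,-1.769,-0.267
T3,22,-1.088,-0.164
T3,22,-0.99,-0.149
T3,22,-3.1,-0.467
T3,22,-4.107,-0.619
T3,22,-1.347,-0.203
T3,22,-2.516,-0.379
T3,22,-3.945,-0.595
T3,22,-3.717,-0.56
T3,22,-0.016,-0.002
T3,22,-2.971,-0.448
T3,22,-2.354,-0.355
T3,22,-1.412,-0.213
T3,22,-2.354,-0.355
T3,22,-1.282,-0.193
T3,22,-0.308,-0.046
T4,21,-3.98,-0.614
T4,21,-2.485,-0.383
T4,21,-3.875,-0.598
T4,21,-3.528,-0.544
T4,21,-2.624,-0.405
T4,21,-1.581,-0.244
T4,21,-2.589,-0.399
T4,21,-2.45,-0.378
T4,21,-1.651,-0.255
T4,21,-2.311,-0.357
T4,21,-1.894,-0.292
T4,21,-3.076,-0.475
T4,21,-2.172,-0.335
T4,21,-3.702,-0.571
T4,21,-0.782,-0.121
T4,21,-3.702,-0.571
T4,21,-0.678,-0.105
T4,21,-4.015,-0.62
T4,21,-3.424,-0.528
T4,21,-1.616,-0.249
T4,21,-1.86,-0.287
T4,21,-0.504,-0.078
T4,21,-1.825,-0.282
T4,21,-1.13,-0.174
T4,21,-3.354,-0.518
T4,21,-4.015,-0.62
T4,21,-1.269,-0.196
T4,21,-1.442,-0.223
T4,21,-1.408,-0.217
T4,21,-0.365,-0.056
T4,21,-2.416,-0.373
T4,21,-3.98,-0.614
T4,21,-3.215,-0.496
T4,21,-1.964,-0.303
T4,21,-2.589,-0.399
T4,21,-3.18,-0.491
T4,21,-1.303,-0.201
T4,21,-1.442,-0.223
T4,21,-0.956,-0.148
T4,21,-0.713,-0.11
T4,21,-1.408,-0.217
T4,21,-1.512,-0.233
T4,21,-0.365,-0.056
T4,21,-3.076,-0.475
T5,22,-3.393,-0.512
T5,22,-0.438,-0.066
T5,22,-1.136,-0.171
T5,22,-3.979,-0.6
T6,21,-3.702,-0.571
T6,21,-0.852,-0.131
T6,21,-2.103,-0.324
T6,21,-3.98,-0.614
T7,22,-3.782,-0.57
T7,22,-2.062,-0.311
T7,22,-3.393,-0.512
T7,22,-3.068,-0.463
T7,22,-1.704,-0.257
T7,22,-1.325,-0.2
T8,21,-3.91,-0.603
T8,21,-3.424,-0.528
T8,21,-3.702,-0.571
T8,21,-3.875,-0.598
T8,21,-1.338,-0.206
T8,21,-1.171,-0.181
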