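network,acc,sen,spe,f1,fnr,fpr,pre,mcc,err,n_params
AlexNet,0.9229,0.9083,0.9215,0.9194,0.4325,0.2963,0.9215,0.8386,0.4377,0.0203
Vgg16,0.9508,0.9301,0.9545,0.9491,0.5,0.4211,0.957,0.8966,0.5495,0.009
Vgg19,0.9261,0.8909,0.9442,0.9215,0.3903,0.3721,0.9498,0.8503,0.4481,0.0086
Inceptionv1,0.9305,0.9367,0.9091,0.9328,0.5245,0.2667,0.923,0.8577,0.4632,0.1771
Inceptionv3,0.9851,0.952,1.0,0.9822,0.5926,1.0,1.0,0.9688,0.8006,0.0519
ResNet18,0.954,0.9541,0.938,0.9575,0.6035,0.3478,0.9492,0.9039,0.566,0.106
ResNet50,0.9796,0.965,0.9773,0.9786,0.6663,0.5926,0.9801,0.9578,0.7467,0.0484
ResNet101,1.0,0.9935,0.9897,0.9993,0.9146,0.7619,0.9922,1.0,1.0,0.0278
InceptionResv2,0.9572,0.9476,0.9504,0.9565,0.5713,0.4,0.9504,0.9073,0.5835,0.0222
Xception,0.9433,0.9629,0.9091,0.9474,0.653,0.2667,0.9197,0.8802,0.5141,0.0541
DenseNet201,0.9958,1.0,0.9752,1.0,1.0,0.5714,0.9858,0.9909,0.934,0.062
MobileNetv2,0.9626,0.9148,0.9917,0.9568,0.4507,0.8,0.9908,0.9246,0.6159,0.3543
ShuffleNet,0.9122,0.8624,0.9442,0.9072,0.3368,0.3721,0.9571,0.8273,0.406,0.8857
NasnetMobile,0.9176,0.8647,0.9525,0.9073,0.3405,0.4103,0.9497,0.8328,0.4214,0.234
NasnetLarge,0.9679,0.9432,0.9752,0.9681,0.5515,0.5714,0.9785,0.9312,0.6513,0.0139
DarkNet19,0.9198,0.8668,0.9545,0.913,0.344,0.4211,0.9491,0.8316,0.4278,0.0596
DarkNet53,0.9454,0.8974,0.9752,0.9393,0.4051,0.5714,0.972,0.8866,0.5236,0.0298
EfficientNetB0,0.9208,0.9127,0.9132,0.9212,0.4445,0.2759,0.9152,0.8303,0.4311,0.234
SqueezeNet,0.8973,0.9279,0.8533,0.9028,0.4921,0.1839,0.8671,0.783,0.3687,1.0
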