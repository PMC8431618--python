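network,fold1,fold2,fold3,fold4,fold5
AlexNet,78.28,89.9,86.87,90.4,89.9
Vgg16,82.32,86.87,86.87,95.96,96.46
Vgg19,79.8,80.81,90.4,89.39,96.46
Inceptionv1,82.32,84.85,83.84,91.92,95.96
Inceptionv3,79.8,90.91,96.97,99.49,97.47
ResNet18,82.83,85.35,92.93,92.42,96.46
ResNet50,81.31,90.91,92.93,97.98,98.99
ResNet101,81.82,94.44,96.97,98.99,99.49
InceptionResv2,77.27,88.89,93.43,93.94,97.98
Xception,78.28,86.87,90.91,93.43,95.45
DenseNet201,86.36,91.94,96.46,97.98,97.47
MobileNetv2,81.31,86.87,89.9,97.47,98.48
ShuffleNet,77.27,83.84,84.85,88.38,95.96
NasnetMobile,78.28,86.36,85.86,85.86,96.46
NasnetLarge,80.3,88.89,92.93,96.46,97.98
DarkNet19,81.31,85.86,84.85,90.91,90.91
DarkNet53,79.29,87.37,91.41,93.94,93.94
EfficientNetB0,84.34,83.84,85.35,88.89,91.92
SqueezeNet,82.32,84.85,82.32,85.86,87.88
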