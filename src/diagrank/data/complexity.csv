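network,n_params
AlexNet,61.0
Vgg16,138.0
Vgg19,144.0
Inceptionv1,7.0
Inceptionv3,23.9
ResNet18,11.7
ResNet50,25.6
ResNet101,44.6
InceptionResv2,55.9
Xception,22.9
DenseNet201,20.0
MobileNetv2,3.5
ShuffleNet,1.4
NasnetMobile,5.3
NasnetLarge,88.9
DarkNet19,20.8
DarkNet53,41.6
EfficientNetB0,5.3
SqueezeNet,1.24
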